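"""Synthetic LASI-like cohort generator.

Each participant carries a latent frailty structure: an age-group score
``s_a`` and a shared person factor ``U ~ N(0, 1)``.  The latent propensity
for deficit ``c`` is

    X_c = b_c * s_a + r_c * U + sqrt(1 - r_c^2) * eps_c,

so that within an age group each X_c is standard normal around ``b_c * s_a``
and deficits co-occur through U.  Deficit flags correspond to ``X_c >= t_c``
where ``t_c`` is solved so the sex-level marginal matches the target
prevalence exactly in expectation.  Questionnaire categories are ordered
slices of X_c; grip strength is a decreasing and walk time an increasing
monotone map of X_c, so downstream quantile dichotomization at the target
marginal recovers the same flags.

Age loadings, factor loadings, age scores and the age mix default to values
calibrated against published LASI Wave-1 estimates (see ``docs/methods.md``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import (
    ACTIVITY_LEVELS,
    AGE_GROUPS,
    COLUMNS,
    EXHAUSTION_LEVELS,
    FRAILTY_RAW_COLUMNS,
    SEXES,
    empty_cohort,
    validate_cohort,
)
from .config import COMPONENTS, GeneratorConfig
from .errors import ConfigurationError

# anthropometry and measurement-scale constants (per sex)
_GRIP_BASE = {"male": 28.0, "female": 19.0}   # kg at X_G = 0
_GRIP_SCALE = {"male": 6.0, "female": 5.0}    # kg per latent sd
_WALK_LOGBASE = 1.60                          # log seconds at X_W = 0 (~5 s / 4 m)
_WALK_LOGSCALE = 0.35
_BMI = {"male": (21.8, 3.6), "female": (22.4, 4.2)}
_HEIGHT = {"male": (163.0, 6.2), "female": (150.5, 5.9)}

# splits of the flagged / unflagged probability mass into response categories
# (ordered by increasing latent deficit propensity)
_EXH_FLAG_SPLIT = (0.55, 0.45)        # often : most
_EXH_CLEAR_SPLIT = (0.55, 0.45)       # rarely : some
_ACT_FLAG_SPLIT = (0.45, 0.55)        # 1-3/month : hardly ever
_ACT_CLEAR_SPLIT = (0.30, 0.40, 0.30)  # every day : >1/week : 1/week


def _mixture_upper_tail_threshold(
    b: float, scores: np.ndarray, mix: np.ndarray, p: float
) -> float:
    """Solve P(X >= t) = p where X ~ sum_a mix_a * N(b*s_a, 1)."""
    f = lambda t: float(np.sum(mix * stats.norm.sf(t - b * scores))) - p
    lo = float(b * scores.min() - 10)
    hi = float(b * scores.max() + 10)
    return optimize.brentq(f, lo, hi, xtol=1e-12)


def component_thresholds(config: GeneratorConfig, sex: str) -> dict[str, float]:
    """Latent flag threshold t_c per component for one sex."""
    mix = np.asarray(config.age_group_mix[sex], dtype=float)
    scores = np.asarray(config.age_scores[sex], dtype=float)
    return {
        c: _mixture_upper_tail_threshold(
            config.age_loading[sex][c], scores, mix,
            config.target_component_prevalence[sex][c],
        )
        for c in COMPONENTS
    }


def _ordinal_from_latent(
    x: np.ndarray,
    b: float,
    scores: np.ndarray,
    mix: np.ndarray,
    upper_tail_probs: list[float],
    levels: tuple[str, ...],
) -> np.ndarray:
    """Map latent values to ordered categories via mixture-quantile cuts.

    ``upper_tail_probs`` are the P(X >= cut) values of the len(levels)-1 cuts,
    in decreasing-category order (first entry = topmost category).
    """
    cuts = [
        _mixture_upper_tail_threshold(b, scores, mix, p) for p in upper_tail_probs
    ]
    out = np.full(x.shape, levels[0], dtype=object)
    # cuts are descending in probability -> ascending in value
    for level, cut in zip(levels[:0:-1], cuts):
        out[(x >= cut) & (out == levels[0])] = level
    return out


def _symmetric_trials(
    center: np.ndarray, jitter: np.ndarray, lower: float, upper: float
) -> tuple[np.ndarray, np.ndarray]:
    """Two trials center +/- d with d shrunk so both stay in (lower, upper).

    The trial mean equals ``center`` exactly, which keeps the downstream
    quantile dichotomization an exact function of the latent propensity.
    """
    room = np.minimum(center - lower, upper - center)
    d = np.sign(jitter) * np.minimum(np.abs(jitter), 0.98 * room)
    return center + d, center - d


def _generate_sex(config: GeneratorConfig, sex: str, n: int, rng: np.random.Generator) -> pd.DataFrame:
    mix = np.asarray(config.age_group_mix[sex], dtype=float)
    scores = np.asarray(config.age_scores[sex], dtype=float)
    load_age = config.age_loading[sex]
    load_fac = config.liability_loading[sex]
    targets = config.target_component_prevalence[sex]

    age_idx = rng.choice(3, size=n, p=mix / mix.sum())
    u = rng.standard_normal(n)
    x = {}
    for c in COMPONENTS:
        b, r = load_age[c], load_fac[c]
        x[c] = b * scores[age_idx] + r * u + np.sqrt(1 - r * r) * rng.standard_normal(n)

    p_e, p_l, p_p = targets["E"], targets["L"], targets["P"]
    exhaustion = _ordinal_from_latent(
        x["E"], load_age["E"], scores, mix,
        [_EXH_FLAG_SPLIT[1] * p_e, p_e, p_e + _EXH_CLEAR_SPLIT[1] * (1 - p_e)],
        EXHAUSTION_LEVELS,
    )
    t_l = _mixture_upper_tail_threshold(load_age["L"], scores, mix, p_l)
    weight_loss = np.where(x["L"] >= t_l, "yes", "no").astype(object)
    activity = _ordinal_from_latent(
        x["P"], load_age["P"], scores, mix,
        [
            _ACT_FLAG_SPLIT[1] * p_p,
            p_p,
            p_p + _ACT_CLEAR_SPLIT[2] * (1 - p_p),
            p_p + (_ACT_CLEAR_SPLIT[1] + _ACT_CLEAR_SPLIT[2]) * (1 - p_p),
        ],
        ACTIVITY_LEVELS,
    )

    grip = np.clip(_GRIP_BASE[sex] - _GRIP_SCALE[sex] * x["G"], 0.5, None)
    grip1, grip2 = _symmetric_trials(grip, rng.normal(0.0, 1.0, n), 0.0, 90.0)
    walk = np.clip(np.exp(_WALK_LOGBASE + _WALK_LOGSCALE * x["W"]), 1.2, 110.0)
    walk1, walk2 = _symmetric_trials(walk, rng.normal(0.0, 0.2, n), 1.05, 119.0)

    bmi = np.clip(rng.normal(*_BMI[sex], size=n), 10.5, 59.0)
    height = np.clip(rng.normal(*_HEIGHT[sex], size=n), 121.0, 199.0)
    s = config.weight_dispersion
    weight = np.exp(rng.normal(-0.5 * s * s, s, size=n)) if s > 0 else np.ones(n)

    data = {
        "id": np.array([f"{sex[0].upper()}{i:06d}" for i in range(n)], dtype=object),
        "sex": np.full(n, sex, dtype=object),
        "age_group": np.asarray(AGE_GROUPS, dtype=object)[age_idx],
        "weight": weight,
        "bmi": bmi,
        "height": height,
        "grip_trial1": grip1,
        "grip_trial2": grip2,
        "walk_trial1": walk1,
        "walk_trial2": walk2,
        "exhaustion_response": exhaustion,
        "weight_loss_response": weight_loss,
        "activity_frequency": activity,
    }
    for cov, props in config.covariate_marginals[sex].items():
        cats = np.asarray(list(props.keys()), dtype=object)
        pr = np.asarray(list(props.values()), dtype=float)
        data[cov] = cats[rng.choice(len(cats), size=n, p=pr / pr.sum())]
    return pd.DataFrame(data, columns=list(COLUMNS))


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a seeded synthetic cohort with the configured structure."""
    if config.n_male + config.n_female == 0:
        return empty_cohort()
    seq = np.random.SeedSequence(config.seed)
    parts = []
    for sex, n, child in zip(SEXES, (config.n_male, config.n_female), seq.spawn(2)):
        if n:
            parts.append(_generate_sex(config, sex, n, np.random.default_rng(child)))
    df = pd.concat(parts, ignore_index=True)
    return validate_cohort(df)


def target_cutoff_proportions(config: GeneratorConfig) -> dict[tuple[str, str], float]:
    """Grip/walk cutoff proportions matching the generator's target marginals.

    Emulates performance-measure cutoffs anchored in a reference population
    wider than the analytic sample: the fraction of this cohort falling past
    such a cutoff is the target prevalence, not the within-cohort quintile.
    """
    return {
        (measure, sex): config.target_component_prevalence[sex][comp]
        for measure, comp in (("grip", "G"), ("walk", "W"))
        for sex in SEXES
    }


def inject_missingness(cohort: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Set each raw frailty field independently missing with probability rate."""
    if not 0 <= rate <= 1:
        raise ConfigurationError(f"missingness rate {rate!r} outside [0, 1]")
    out = cohort.copy()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    for col in FRAILTY_RAW_COLUMNS:
        mask = rng.random(len(out)) < rate
        if out[col].dtype == object:
            out.loc[mask, col] = np.nan
        else:
            out.loc[mask, col] = np.nan
    return out
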