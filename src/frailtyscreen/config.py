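"""Configuration dataclasses for generation, scoring and evaluation.

Defaults encode the study conditions the package emulates: a LASI-Wave-1-like
cohort of older Indian adults (14,885 male / 16,093 female) whose deficit
marginals, age gradients and deficit co-occurrence were calibrated to the
published national estimates (see :mod:`frailtyscreen.published` and
``docs/methods.md``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

from scipy import stats

from . import published
from .errors import ConfigurationError

COMPONENTS = published.COMPONENTS
SEXES = published.SEXES

# Calibrated latent-structure defaults (per sex):
#   age_scores   s_a for age groups 60-69 / 70-79 / 80+
#   age_loading  b_c: probit slope of deficit c on the age score
#   factor_loading r_c: signed loading of deficit c on the shared person
#                      factor U ~ N(0,1); residual sd is sqrt(1 - r_c^2)
AGE_MIX_DEFAULT = {
    "male": (0.5877, 0.3126, 0.0997),
    "female": (0.5975, 0.3190, 0.0835),
}
AGE_SCORES_DEFAULT = {
    "male": (0.0, 1.0, 2.1281),
    "female": (0.0, 1.0, 1.9589),
}
AGE_LOADING_DEFAULT = {
    "male": {"E": 0.0262, "G": 0.5181, "W": 0.6149, "L": 0.0174, "P": 0.4439},
    "female": {"E": 0.0773, "G": 0.5277, "W": 0.5985, "L": -0.0025, "P": 0.3787},
}
FACTOR_LOADING_DEFAULT = {
    "male": {"E": 0.9500, "G": -0.2068, "W": 0.5677, "L": -0.6309, "P": -0.1132},
    "female": {"E": 0.9500, "G": -0.1715, "W": 0.4649, "L": -0.2546, "P": -0.4864},
}


def _check_proportion(name: str, value: float, open_interval: bool = False) -> None:
    lo_ok = value > 0 if open_interval else value >= 0
    hi_ok = value < 1 if open_interval else value <= 1
    if not (lo_ok and hi_ok):
        raise ConfigurationError(f"{name} = {value!r} outside the unit interval")


def _check_simplex(name: str, props) -> None:
    vals = list(props.values()) if isinstance(props, Mapping) else list(props)
    for v in vals:
        _check_proportion(name, float(v))
    if abs(sum(vals) - 1.0) > 1e-9:
        raise ConfigurationError(f"{name} proportions sum to {sum(vals)!r}, not 1")


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic LASI-like cohort generator."""

    n_male: int = published.N_MALE
    n_female: int = published.N_FEMALE
    seed: int = 0
    target_component_prevalence: dict = field(
        default_factory=lambda: {s: published.component_targets(s) for s in SEXES}
    )
    liability_loading: dict = field(
        default_factory=lambda: {s: dict(FACTOR_LOADING_DEFAULT[s]) for s in SEXES}
    )
    age_loading: dict = field(
        default_factory=lambda: {s: dict(AGE_LOADING_DEFAULT[s]) for s in SEXES}
    )
    age_group_mix: dict = field(
        default_factory=lambda: {s: tuple(AGE_MIX_DEFAULT[s]) for s in SEXES}
    )
    age_scores: dict = field(
        default_factory=lambda: {s: tuple(AGE_SCORES_DEFAULT[s]) for s in SEXES}
    )
    covariate_marginals: dict = field(
        default_factory=lambda: {s: published.covariate_marginals(s) for s in SEXES}
    )
    weight_dispersion: float = 0.3

    def __post_init__(self) -> None:
        if self.n_male < 0 or self.n_female < 0:
            raise ConfigurationError("n_male and n_female must be >= 0")
        if self.weight_dispersion < 0:
            raise ConfigurationError("weight_dispersion must be >= 0")
        for sex in SEXES:
            for comp, p in self.target_component_prevalence[sex].items():
                _check_proportion(
                    f"target_component_prevalence[{sex}][{comp}]", p, open_interval=True
                )
            for comp, r in self.liability_loading[sex].items():
                if not -1 < r < 1:
                    raise ConfigurationError(
                        f"liability_loading[{sex}][{comp}] = {r!r} outside (-1, 1)"
                    )
            _check_simplex(f"age_group_mix[{sex}]", self.age_group_mix[sex])
            for cov, props in self.covariate_marginals[sex].items():
                _check_simplex(f"covariate_marginals[{sex}][{cov}]", props)


@dataclass
class ScoringConfig:
    """How raw measures become deficits, a 0-5 score and the frail label."""

    frail_threshold: int = 3
    quintile_proportion: float = 0.20
    #: optional per-(measure, sex) overrides of the cutoff proportion, e.g.
    #: {("grip", "male"): 0.7907}; used to emulate cutoffs anchored in a
    #: reference population wider than the analytic sample.
    proportion_overrides: dict = field(default_factory=dict)
    grip_strata: str = "sex_bmi_quartile"  # or "sex_bmi_median"
    walk_strata: str = "sex_height_median"
    walk_direction: str = "slowest_flagged"  # or "fastest_flagged"
    quantile_weighting: str = "unweighted"  # or "survey_weighted"
    tie_rule: str = "flag_at_or_below"  # or "flag_strictly_below"

    def __post_init__(self) -> None:
        if not 1 <= self.frail_threshold <= 5:
            raise ConfigurationError("frail_threshold must be in 1..5")
        _check_proportion("quintile_proportion", self.quintile_proportion, True)
        for (measure, sex), p in self.proportion_overrides.items():
            if measure not in ("grip", "walk") or sex not in SEXES:
                raise ConfigurationError(
                    f"proportion_overrides key {(measure, sex)!r} invalid"
                )
            _check_proportion(f"proportion_overrides[{measure},{sex}]", p, True)
        for attr, choices in [
            ("grip_strata", ("sex_bmi_quartile", "sex_bmi_median")),
            ("walk_strata", ("sex_height_median",)),
            ("walk_direction", ("slowest_flagged", "fastest_flagged")),
            ("quantile_weighting", ("unweighted", "survey_weighted")),
            ("tie_rule", ("flag_at_or_below", "flag_strictly_below")),
        ]:
            if getattr(self, attr) not in choices:
                raise ConfigurationError(
                    f"{attr} = {getattr(self, attr)!r}; expected one of {choices}"
                )

    def proportion_for(self, measure: str, sex: str) -> float:
        return self.proportion_overrides.get((measure, sex), self.quintile_proportion)


@dataclass
class WilsonParams:
    """Confidence level for the continuity-corrected Wilson score interval."""

    confidence: float = 0.95
    z: float | None = None

    def __post_init__(self) -> None:
        _check_proportion("confidence", self.confidence, open_interval=True)
        if self.z is None:
            # two-sided normal quantile; 1.959964 at 95%
            self.z = float(stats.norm.ppf(0.5 + self.confidence / 2))
        if self.z <= 0:
            raise ConfigurationError("z must be > 0")


@dataclass
class RunConfig:
    """End-to-end pipeline run: generation (or input), scoring, evaluation."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    wilson: WilsonParams = field(default_factory=WilsonParams)
    input_path: str | None = None  # read a cohort instead of simulating
    output_dir: str = "frailtyscreen-run"
    missingness_rate: float = 0.0
    pair_rule: str = "parallel_or"
    weighted_tables: bool = False  # weight the 2x2 cells by survey weight
    #: derive grip/walk cutoff proportions from the generator's target
    #: marginals (reference-population emulation) instead of the literal
    #: bottom-quintile rule; only meaningful for synthetic runs.
    cutoffs_from_targets: bool = True
    make_figure: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        _check_proportion("missingness_rate", self.missingness_rate)
        if self.pair_rule not in ("parallel_or", "serial_and"):
            raise ConfigurationError(f"pair_rule = {self.pair_rule!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        # JSON-friendly keys for the overrides map
        d["scoring"]["proportion_overrides"] = {
            f"{m}:{s}": p for (m, s), p in self.scoring.proportion_overrides.items()
        }
        return d
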