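"""Survey-weighted descriptive tables and chi-square tests.

Reproduces the shape of the background-characteristics table (covariate
distribution by age group within sex, weighted percents, chi-square
p-value) and the deficit-prevalence table (unweighted N flagged and
weighted percent per age group and overall, per sex).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import AGE_GROUPS, COVARIATE_LEVELS, SEXES
from .config import COMPONENTS
from .errors import ConfigurationError
from .published import COMPONENT_NAMES


def weighted_percent(values, weights) -> pd.Series:
    """Survey-weighted percentage distribution of a categorical variable.

    percent(c) = 100 * sum(w_i : x_i = c) / sum(w_i)
    """
    vals = pd.Series(values).reset_index(drop=True)
    w = pd.Series(weights, dtype=float).reset_index(drop=True)
    if len(vals) == 0:
        raise ConfigurationError("weighted_percent of empty input")
    if len(vals) != len(w):
        raise ConfigurationError("values and weights differ in length")
    if (w <= 0).any():
        raise ConfigurationError("weights must be positive")
    out = w.groupby(vals).sum() * (100.0 / w.sum())
    return out


def chi_square_test(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a contingency table.

    Returns (statistic, df, p).  Expected counts are row*col/total; no
    continuity correction (matching the source analysis's plain chi-square).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ConfigurationError("chi-square needs an r x c table with r, c >= 2")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ConfigurationError("zero marginal row or column")
    res = stats.chi2_contingency(obs, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def format_p(p: float) -> str:
    """Report style: three decimals with a '<0.001' floor."""
    return "<0.001" if p < 0.001 else f"{p:.3f}"


@dataclass
class WeightedCrosstab:
    """One descriptive panel: N and weighted % per category x age group."""

    variable: str
    sex: str
    counts: pd.DataFrame    # categories x (age groups + 'total'), unweighted N
    percents: pd.DataFrame  # same shape, weighted %
    chi2: float | None = None
    df: int | None = None
    p_value: float | None = None


def _crosstab(
    df: pd.DataFrame, variable: str, sex: str, with_test: bool
) -> WeightedCrosstab:
    sub = df[df["sex"] == sex]
    if sub.empty:
        raise ConfigurationError(f"no rows for sex {sex!r}")
    cats = [c for c in _level_order(variable) if (sub[variable] == c).any()]
    cols = list(AGE_GROUPS) + ["total"]
    counts = pd.DataFrame(0, index=cats, columns=cols, dtype=int)
    pct = pd.DataFrame(np.nan, index=cats, columns=cols, dtype=float)
    for col in cols:
        m = sub if col == "total" else sub[sub["age_group"] == col]
        if m.empty:
            continue
        n = m.groupby(variable)["id"].count()
        w = weighted_percent(m[variable], m["weight"])
        for c in cats:
            counts.loc[c, col] = int(n.get(c, 0))
            pct.loc[c, col] = float(w.get(c, 0.0))
    out = WeightedCrosstab(variable, sex, counts, pct)
    if with_test and len(cats) >= 2:
        obs = counts[list(AGE_GROUPS)].to_numpy()
        obs = obs[:, obs.sum(axis=0) > 0]
        if obs.shape[1] >= 2 and (obs.sum(axis=1) > 0).all():
            out.chi2, out.df, out.p_value = chi_square_test(obs)
    return out


def _level_order(variable: str) -> tuple[str, ...]:
    if variable in COVARIATE_LEVELS:
        return COVARIATE_LEVELS[variable]
    return ("0", "1")


def build_table1(cohort: pd.DataFrame) -> dict[tuple[str, str], WeightedCrosstab]:
    """Background-characteristics panels: one per (covariate, sex).

    Each panel cross-tabulates the covariate against age group with
    unweighted N, survey-weighted percents, and a chi-square test of
    age-group association within sex.
    """
    _require(cohort, ("sex", "age_group"))
    out = {}
    for cov in COVARIATE_LEVELS:
        for sex in SEXES:
            if (cohort["sex"] == sex).any():
                out[(cov, sex)] = _crosstab(cohort, cov, sex, with_test=True)
    return out


def build_table2(
    cohort: pd.DataFrame, flags: pd.DataFrame
) -> dict[tuple[str, str], WeightedCrosstab]:
    """Deficit-prevalence panels: flagged N and weighted % by age and sex.

    One panel per component plus the combined frail label; the percent cell
    is the weighted prevalence of the deficit within that age x sex stratum.
    """
    _require(cohort, ("sex", "age_group", "weight"))
    joined = flags.merge(
        cohort[["id"]], on="id", how="inner", validate="one_to_one"
    )
    out = {}
    items = [(c, COMPONENT_NAMES[c]) for c in COMPONENTS] + [("frail", "frailty_combined")]
    for col, name in items:
        work = joined.rename(columns={col: "_flag"})[["_flag", "sex", "age_group", "weight", "id"]]
        work["_flag"] = work["_flag"].astype(int).astype(str)
        for sex in SEXES:
            if not (work["sex"] == sex).any():
                continue
            panel = _crosstab(work, "_flag", sex, with_test=False)
            flagged = WeightedCrosstab(
                variable=name,
                sex=sex,
                counts=panel.counts.loc[["1"]] if "1" in panel.counts.index
                else panel.counts.iloc[:0],
                percents=panel.percents.loc[["1"]] if "1" in panel.percents.index
                else panel.percents.iloc[:0],
            )
            out[(name, sex)] = flagged
    return out


def table1_frame(panels: dict[tuple[str, str], WeightedCrosstab]) -> pd.DataFrame:
    """Flatten covariate panels into one tidy CSV-ready frame."""
    rows = []
    for (cov, sex), panel in sorted(panels.items()):
        for cat in panel.counts.index:
            row = {"sex": sex, "variable": cov, "category": cat}
            for col in panel.counts.columns:
                row[f"n_{col}"] = panel.counts.loc[cat, col]
                row[f"wpct_{col}"] = panel.percents.loc[cat, col]
            row["p_value"] = (
                format_p(panel.p_value) if panel.p_value is not None else ""
            )
            rows.append(row)
    return pd.DataFrame(rows)


def table2_frame(panels: dict[tuple[str, str], WeightedCrosstab]) -> pd.DataFrame:
    """Flatten prevalence panels into one tidy CSV-ready frame."""
    rows = []
    order = [COMPONENT_NAMES[c] for c in COMPONENTS] + ["frailty_combined"]
    for name in order:
        for sex in SEXES:
            panel = panels.get((name, sex))
            if panel is None or panel.counts.empty:
                continue
            row = {"sex": sex, "component": name}
            for col in panel.counts.columns:
                row[f"n_{col}"] = int(panel.counts.iloc[0][col])
                row[f"wpct_{col}"] = float(panel.percents.iloc[0][col])
            rows.append(row)
    return pd.DataFrame(rows)


def _require(df: pd.DataFrame, cols: tuple[str, ...]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing column(s): {', '.join(missing)}")
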