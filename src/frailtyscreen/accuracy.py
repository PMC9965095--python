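"""Screening accuracy of deficit markers against the composite frail label.

Each single deficit, and every unordered pair of deficits combined in
parallel (positive if either is positive) or in series (positive only if
both are), is evaluated as a screening marker for the composite phenotype
via a 2x2 contingency table:

    sensitivity = TP/(TP+FN)    specificity = TN/(TN+FP)
    PPV = TP/(TP+FP)            NPV = TN/(TN+FN)
    prevalence = (TP+FN)/n

Every point estimate carries a Wilson score interval with continuity
correction (Newcombe's closed form), the interval the source survey
literature reports for screening proportions.  Predictive values obey the
Bayes identities

    PPV = se*pi / (se*pi + (1-sp)(1-pi))
    NPV = sp*(1-pi) / (sp*(1-pi) + (1-se)*pi)

with se = sensitivity, sp = specificity, pi = prevalence; these are exposed
separately as a cross-column consistency check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import COMPONENTS, WilsonParams
from .errors import ConfigurationError

PAIR_RULES = ("parallel_or", "serial_and")


@dataclass(frozen=True)
class MarkerDefinition:
    """A screening marker: one deficit, or two combined by a rule."""

    name: str
    components: tuple[str, ...]
    rule: str = "single"

    def __post_init__(self) -> None:
        unknown = [c for c in self.components if c not in COMPONENTS]
        if unknown:
            raise ConfigurationError(f"unknown component letter(s) {unknown!r}")
        if self.rule == "single" and len(self.components) != 1:
            raise ConfigurationError("single markers take exactly one component")
        if self.rule in PAIR_RULES and len(self.components) != 2:
            raise ConfigurationError(f"{self.rule} markers take exactly two components")
        if self.rule not in ("single", *PAIR_RULES):
            raise ConfigurationError(f"unknown rule {self.rule!r}")


def single_marker(component: str) -> MarkerDefinition:
    return MarkerDefinition(component, (component,), "single")


def pair_marker(c1: str, c2: str, rule: str = "parallel_or") -> MarkerDefinition:
    a, b = sorted((c1, c2))
    op = "|" if rule == "parallel_or" else "&"
    return MarkerDefinition(f"{a}{op}{b}", (a, b), rule)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """TP/FP/FN/TN cells; floats so cells may hold survey-weight sums."""

    tp: float
    fp: float
    fn: float
    tn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ConfigurationError("2x2 cells must be non-negative")
        if self.n <= 0:
            raise ConfigurationError("2x2 table is empty")

    @property
    def n(self) -> float:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricEstimate:
    point: float
    lower: float
    upper: float


@dataclass
class DiagnosticMetrics:
    """The five accuracy statistics for one marker in one stratum.

    A metric whose denominator is zero is None, with the reason recorded in
    ``undefined`` instead of being coerced to 0 or 1.
    """

    marker: MarkerDefinition
    stratum: str
    table: ContingencyTable2x2
    sensitivity: MetricEstimate | None
    specificity: MetricEstimate | None
    ppv: MetricEstimate | None
    npv: MetricEstimate | None
    prevalence: MetricEstimate | None
    undefined: dict = field(default_factory=dict)


def wilson_cc(successes: float, n: float, params: WilsonParams | None = None) -> tuple[float, float]:
    """Wilson score interval with continuity correction (Newcombe).

    Closed-form bounds of the continuity-corrected score test inversion:

        L = (2np + z^2 - 1 - z*sqrt(z^2 - 2 - 1/n + 4p(n(1-p)+1))) / (2(n+z^2))
        U = (2np + z^2 + 1 + z*sqrt(z^2 + 2 - 1/n + 4p(n(1-p)-1))) / (2(n+z^2))

    with p = successes/n, clipped to [0, 1]; L = 0 when p = 0 and U = 1 when
    p = 1 by convention.
    """
    params = params or WilsonParams()
    if n < 1:
        raise ConfigurationError("wilson_cc requires n >= 1")
    if not 0 <= successes <= n:
        raise ConfigurationError("successes must lie in [0, n]")
    z = params.z
    p = successes / n
    denom = 2 * (n + z * z)
    if p == 0:
        lower = 0.0
    else:
        rad = z * z - 2 - 1 / n + 4 * p * (n * (1 - p) + 1)
        lower = (2 * n * p + z * z - 1 - z * math.sqrt(max(rad, 0.0))) / denom
    if p == 1:
        upper = 1.0
    else:
        rad = z * z + 2 - 1 / n + 4 * p * (n * (1 - p) - 1)
        upper = (2 * n * p + z * z + 1 + z * math.sqrt(max(rad, 0.0))) / denom
    return max(lower, 0.0), min(upper, 1.0)


def apply_marker(flags: pd.DataFrame, marker: MarkerDefinition) -> np.ndarray:
    """Per-row 0/1 marker positivity from the component flag columns."""
    cols = [flags[c].to_numpy(int) for c in marker.components]
    if marker.rule == "single":
        return cols[0].copy()
    if marker.rule == "parallel_or":
        return (cols[0] | cols[1]).astype(int)
    return (cols[0] & cols[1]).astype(int)


def build_contingency(
    positivity: Sequence[int],
    frail: Sequence[int],
    weights: Sequence[float] | None = None,
) -> ContingencyTable2x2:
    """Cross-classify marker positivity against the frail label."""
    pos = np.asarray(positivity)
    ref = np.asarray(frail)
    if pos.shape != ref.shape:
        raise ConfigurationError(
            f"length mismatch: {pos.shape[0]} positivity vs {ref.shape[0]} labels"
        )
    w = np.ones(len(pos)) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != pos.shape:
        raise ConfigurationError("weights length mismatch")
    pos = pos.astype(bool)
    ref = ref.astype(bool)
    return ContingencyTable2x2(
        tp=float(w[pos & ref].sum()),
        fp=float(w[pos & ~ref].sum()),
        fn=float(w[~pos & ref].sum()),
        tn=float(w[~pos & ~ref].sum()),
    )


def _estimate(num: float, den: float, params: WilsonParams) -> MetricEstimate | None:
    if den == 0:
        return None
    lo, hi = wilson_cc(num, den, params)
    return MetricEstimate(num / den, lo, hi)


def metrics_from_table(
    t: ContingencyTable2x2,
    params: WilsonParams | None = None,
    marker: MarkerDefinition | None = None,
    stratum: str = "",
) -> DiagnosticMetrics:
    """The five accuracy statistics with Wilson-CC intervals.

    Each interval uses its metric's own denominator (diseased for
    sensitivity, non-diseased for specificity, test-positive for PPV,
    test-negative for NPV, the full sample for prevalence).
    """
    params = params or WilsonParams()
    pieces = {
        "sensitivity": (t.tp, t.tp + t.fn),
        "specificity": (t.tn, t.tn + t.fp),
        "ppv": (t.tp, t.tp + t.fp),
        "npv": (t.tn, t.tn + t.fn),
        "prevalence": (t.tp + t.fn, t.n),
    }
    est = {k: _estimate(num, den, params) for k, (num, den) in pieces.items()}
    undefined = {
        k: f"zero denominator ({k})" for k, v in est.items() if v is None
    }
    return DiagnosticMetrics(
        marker=marker or MarkerDefinition("marker", ("E",), "single"),
        stratum=stratum,
        table=t,
        undefined=undefined,
        **est,
    )


def ppv_from_bayes(sens: float, spec: float, prev: float) -> float:
    """Positive predictive value from sensitivity, specificity, prevalence."""
    for name, v in (("sens", sens), ("spec", spec), ("prev", prev)):
        if not 0 <= v <= 1:
            raise ConfigurationError(f"{name} = {v!r} outside [0, 1]")
    den = sens * prev + (1 - spec) * (1 - prev)
    if den == 0:
        raise ZeroDivisionError("no test positives: PPV undefined")
    return sens * prev / den


def npv_from_bayes(sens: float, spec: float, prev: float) -> float:
    """Negative predictive value from sensitivity, specificity, prevalence."""
    for name, v in (("sens", sens), ("spec", spec), ("prev", prev)):
        if not 0 <= v <= 1:
            raise ConfigurationError(f"{name} = {v!r} outside [0, 1]")
    den = spec * (1 - prev) + (1 - sens) * prev
    if den == 0:
        raise ZeroDivisionError("no test negatives: NPV undefined")
    return spec * (1 - prev) / den


def all_markers(pair_rule: str = "parallel_or") -> list[MarkerDefinition]:
    """The 5 single markers plus the 10 unordered pair markers."""
    if pair_rule not in PAIR_RULES:
        raise ConfigurationError(f"unknown pair rule {pair_rule!r}")
    singles = [single_marker(c) for c in COMPONENTS]
    pairs = [pair_marker(a, b, pair_rule) for a, b in combinations(COMPONENTS, 2)]
    return singles + pairs


def evaluate_all_markers(
    flags: pd.DataFrame,
    params: WilsonParams | None = None,
    by_sex: bool = True,
    pair_rule: str = "parallel_or",
    weighted: bool = False,
) -> list[DiagnosticMetrics]:
    """Evaluate every single and pair marker, optionally per sex stratum.

    Output order is deterministic: stratum, then marker name.
    """
    params = params or WilsonParams()
    if by_sex:
        strata = [(s, flags[flags["sex"] == s]) for s in ("male", "female")]
        strata = [(s, f) for s, f in strata if len(f)]
        if not strata:
            raise ConfigurationError("no rows in any sex stratum")
    else:
        strata = [("all", flags)]
    out = []
    for stratum, sub in strata:
        if sub.empty:
            raise ConfigurationError(f"empty stratum {stratum!r}")
        w = sub["weight"].to_numpy(float) if weighted else None
        frail = sub["frail"].to_numpy(int)
        for marker in sorted(all_markers(pair_rule), key=lambda m: m.name):
            pos = apply_marker(sub, marker)
            t = build_contingency(pos, frail, w)
            out.append(metrics_from_table(t, params, marker, stratum))
    return out


def metrics_table(metrics: Iterable[DiagnosticMetrics]) -> pd.DataFrame:
    """Flatten metric objects into the report table (raw proportions)."""
    rows = []
    for m in metrics:
        row: dict = {
            "sex": m.stratum,
            "marker": m.marker.name,
            "rule": m.marker.rule,
        }
        for key, attr in [
            ("sensitivity", m.sensitivity),
            ("specificity", m.specificity),
            ("ppv", m.ppv),
            ("npv", m.npv),
            ("prevalence", m.prevalence),
        ]:
            short = {"sensitivity": "sens", "specificity": "spec",
                     "prevalence": "prev"}.get(key, key)
            if attr is None:
                row[key] = np.nan
                row[f"{short}_lo"] = np.nan
                row[f"{short}_hi"] = np.nan
            else:
                row[key] = attr.point
                row[f"{short}_lo"] = attr.lower
                row[f"{short}_hi"] = attr.upper
        row["n"] = m.table.n
        rows.append(row)
    return pd.DataFrame(rows)


def rank_components(
    metrics: Iterable[DiagnosticMetrics],
    criterion: str = "prevalence",
    stratum: str | None = None,
) -> list[tuple[str, float]]:
    """Single components sorted descending by marker prevalence or sensitivity.

    ``criterion='prevalence'`` ranks by the fraction of the sample positive
    on the component itself (its discriminant share), not by the composite
    phenotype prevalence.  Ties break alphabetically.
    """
    if criterion not in ("prevalence", "sensitivity"):
        raise ConfigurationError(f"unknown ranking criterion {criterion!r}")
    vals: dict[str, float] = {}
    for m in metrics:
        if m.marker.rule != "single":
            continue
        if stratum is not None and m.stratum != stratum:
            continue
        comp = m.marker.components[0]
        if criterion == "prevalence":
            t = m.table
            vals[comp] = (t.tp + t.fp) / t.n  # marker-positive share
        else:
            if m.sensitivity is None:
                continue
            vals[comp] = m.sensitivity.point
    order = sorted(vals.items(), key=lambda kv: (-kv[1], kv[0]))
    return order
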