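"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: the interval oracle
inverts the continuity-corrected score test numerically, the quantile oracle
scans sorted values, and the chi-square oracle is the textbook formula.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize


def wilson_cc_oracle(successes: int, n: int, z: float = 1.959964) -> tuple[float, float]:
    """Invert the continuity-corrected score test numerically.

    The interval is {p : |p_hat - p| - 1/(2n) <= z*sqrt(p(1-p)/n)} clipped to
    [0, 1], with the conventional 0 / 1 boundaries at p_hat = 0 / 1.
    """
    p_hat = successes / n

    def g_lower(p):  # zero of this in (0, p_hat) is the lower bound
        return (p_hat - p - 1 / (2 * n)) - z * math.sqrt(p * (1 - p) / n)

    def g_upper(p):  # zero of this in (p_hat, 1) is the upper bound
        return (p - p_hat - 1 / (2 * n)) - z * math.sqrt(p * (1 - p) / n)

    if p_hat == 0:
        lower = 0.0
    elif g_lower(1e-15) <= 0:
        lower = 0.0
    else:
        lower = optimize.brentq(g_lower, 1e-15, p_hat, xtol=1e-14)
    if p_hat == 1:
        upper = 1.0
    elif g_upper(1 - 1e-15) <= 0:
        upper = 1.0
    else:
        upper = optimize.brentq(g_upper, p_hat, 1 - 1e-15, xtol=1e-14)
    return lower, upper


def lower_quantile_oracle(values, p: float) -> float:
    """Smallest value whose cumulative fraction is >= p (scan of sorted data)."""
    vals = sorted(values)
    n = len(vals)
    for i, v in enumerate(vals):
        # cumulative fraction of observations <= v
        frac = sum(1 for x in vals if x <= v) / n
        if frac >= p:
            return v
    return vals[-1]


def upper_quantile_oracle(values, p: float) -> float:
    """Largest value whose upper-tail fraction is >= p."""
    vals = sorted(values, reverse=True)
    n = len(vals)
    for v in vals:
        frac = sum(1 for x in vals if x >= v) / n
        if frac >= p:
            return v
    return vals[-1]


def chi2_textbook_oracle(table) -> tuple[float, int]:
    """Pearson chi-square by the definition: sum (O-E)^2/E, E = row*col/n."""
    obs = np.asarray(table, dtype=float)
    n = obs.sum()
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    stat = 0.0
    for i in range(obs.shape[0]):
        for j in range(obs.shape[1]):
            e = rows[i] * cols[j] / n
            stat += (obs[i, j] - e) ** 2 / e
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return stat, df


def metrics_by_enumeration(positivity, frail):
    """Direct counting of the five accuracy statistics from paired vectors."""
    tp = sum(1 for m, f in zip(positivity, frail) if m and f)
    fp = sum(1 for m, f in zip(positivity, frail) if m and not f)
    fn = sum(1 for m, f in zip(positivity, frail) if not m and f)
    tn = sum(1 for m, f in zip(positivity, frail) if not m and not f)
    n = tp + fp + fn + tn

    def safe(num, den):
        return num / den if den else None

    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "sensitivity": safe(tp, tp + fn),
        "specificity": safe(tn, tn + fp),
        "ppv": safe(tp, tp + fp),
        "npv": safe(tn, tn + fn),
        "prevalence": safe(tp + fn, n),
    }
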