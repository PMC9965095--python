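"""Published LASI Wave-1 (2017-18) reference estimates for older adults (60+).

These are the national survey-weighted estimates for the 30,978-person
analytic sample (14,885 male / 16,093 female) that the synthetic cohort
generator emulates: per-component deficit prevalence by age group and sex,
combined frailty-phenotype prevalence (>= 3 of 5 deficits), the published
gender-specific screening-accuracy table for each deficit used as a marker
of the composite phenotype, and the unweighted covariate counts used as
covariate marginals.

Component letters throughout the package:

    E  exhaustion            G  weak grip strength
    W  slow walk time        L  unintentional weight loss
    P  low physical activity
"""

from __future__ import annotations

COMPONENTS = ("E", "G", "W", "L", "P")
COMPONENT_NAMES = {
    "E": "exhaustion",
    "G": "grip_strength",
    "W": "walk_time",
    "L": "weight_loss",
    "P": "physical_activity",
}
SEXES = ("male", "female")
AGE_GROUPS = ("60-69", "70-79", "80+")

N_MALE = 14_885
N_FEMALE = 16_093

# Weighted deficit prevalence (%) by age group, with the all-ages total last.
COMPONENT_PREVALENCE_PCT = {
    "male": {
        "E": (37.04, 39.26, 39.18, 37.94),
        "G": (72.30, 86.84, 95.32, 79.07),
        "W": (8.06, 19.72, 45.23, 15.40),
        "L": (5.76, 5.90, 6.20, 5.85),
        "P": (55.68, 73.14, 85.85, 64.21),
    },
    "female": {
        "E": (37.97, 41.14, 43.92, 39.54),
        "G": (58.54, 77.54, 89.18, 67.09),
        "W": (16.96, 35.43, 58.45, 26.31),
        "L": (5.22, 6.32, 5.10, 5.53),
        "P": (76.94, 87.06, 92.95, 81.63),
    },
}

# Combined frailty (score >= 3) prevalence (%), same layout.
FRAILTY_PREVALENCE_PCT = {
    "male": (19.87, 35.04, 51.34, 27.85),
    "female": (24.81, 41.58, 56.80, 33.16),
}

# Published screening accuracy of each marker against the composite
# phenotype: percent sensitivity, specificity, PPV, NPV and prevalence.
# "grip_and_activity" is the parallel (either-positive) dual marker.
ACCURACY_PCT = {
    ("male", "exhaustion"): dict(sens=73.34, spec=76.90, ppv=52.65, npv=89.18, prev=25.93),
    ("male", "grip_strength"): dict(sens=98.02, spec=32.02, ppv=36.17, npv=97.62, prev=28.21),
    ("male", "walk_time"): dict(sens=46.30, spec=96.63, ppv=84.04, npv=82.43, prev=27.72),
    ("male", "weight_loss"): dict(sens=12.17, spec=98.38, ppv=72.25, npv=76.31, prev=25.80),
    ("male", "physical_activity"): dict(sens=94.75, spec=44.64, ppv=37.41, npv=96.06, prev=25.88),
    ("male", "grip_and_activity"): dict(sens=99.97, spec=14.61, ppv=31.28, npv=99.93, prev=27.99),
    ("female", "exhaustion"): dict(sens=68.07, spec=75.13, ppv=56.52, npv=83.21, prev=32.20),
    ("female", "grip_strength"): dict(sens=93.48, spec=51.34, ppv=51.38, npv=93.47, prev=35.49),
    ("female", "walk_time"): dict(sens=61.92, spec=92.06, ppv=80.75, npv=81.81, prev=34.96),
    ("female", "weight_loss"): dict(sens=10.88, spec=98.32, ppv=75.37, npv=70.03, prev=32.07),
    ("female", "physical_activity"): dict(sens=96.87, spec=26.63, ppv=38.51, npv=94.72, prev=32.17),
    ("female", "grip_and_activity"): dict(sens=99.98, spec=13.48, ppv=38.43, npv=99.92, prev=35.07),
}

# Predictive-value cells whose published 2-dp value is exactly recovered by
# the Bayes identities from the published sensitivity/specificity/prevalence
# of the same row (the well-conditioned cells; input rounding to 2 dp leaves
# the reconstruction on the printed value).  (sex, marker, metric) keys.
WELL_CONDITIONED_BAYES_CELLS = (
    ("male", "grip_strength", "ppv"),
    ("male", "exhaustion", "npv"),
    ("male", "walk_time", "npv"),
    ("male", "physical_activity", "ppv"),
    ("male", "physical_activity", "npv"),
    ("female", "exhaustion", "ppv"),
    ("female", "grip_strength", "ppv"),
    ("female", "grip_strength", "npv"),
    ("female", "physical_activity", "ppv"),
    ("female", "physical_activity", "npv"),
)

# Unweighted covariate counts per sex (category -> N).  Category counts for a
# covariate do not always sum exactly to the sex total because of item
# nonresponse in the source survey; marginals are normalized downstream.
COVARIATE_COUNTS = {
    "male": {
        "residence": {"urban": 4892, "rural": 9993},
        "marital": {"in_wedlock": 12246, "not_in_wedlock": 2639},
        "education": {"none": 5398, "primary": 4441, "secondary": 3240, "higher": 1806},
        "work": {"never_worked": 811, "working": 6281, "not_working": 5784, "retired": 1991},
        "alcohol": {"no": 10227, "yes": 4651},
        "smoking": {"no": 6549, "yes": 8327},
        "adl": {"no": 12323, "yes": 2559},
        "iadl": {"no": 9770, "yes": 5100},
    },
    "female": {
        "residence": {"urban": 5572, "rural": 10521},
        "marital": {"in_wedlock": 7513, "not_in_wedlock": 8580},
        "education": {"none": 11230, "primary": 3012, "secondary": 1291, "higher": 560},
        "work": {"never_worked": 7940, "working": 2951, "not_working": 4846, "retired": 349},
        "alcohol": {"no": 15414, "yes": 679},
        "smoking": {"no": 12417, "yes": 3670},
        "adl": {"no": 12319, "yes": 3772},
        "iadl": {"no": 7729, "yes": 8333},
    },
}


def component_targets(sex: str) -> dict[str, float]:
    """All-ages target prevalence of each deficit as a proportion."""
    return {c: COMPONENT_PREVALENCE_PCT[sex][c][3] / 100.0 for c in COMPONENTS}


def covariate_marginals(sex: str) -> dict[str, dict[str, float]]:
    """Covariate category proportions per sex, normalized to sum to 1."""
    out: dict[str, dict[str, float]] = {}
    for cov, counts in COVARIATE_COUNTS[sex].items():
        total = float(sum(counts.values()))
        props = {k: v / total for k, v in counts.items()}
        # exact renormalization so validation's 1e-9 sum check holds
        s = sum(props.values())
        out[cov] = {k: v / s for k, v in props.items()}
    return out
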