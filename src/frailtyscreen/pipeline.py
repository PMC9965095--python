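"""End-to-end orchestration: simulate (or read) -> score -> evaluate -> describe.

A run writes, under the configured output directory:

* ``cohort.csv``    the synthetic cohort (when simulated)
* ``cutoffs.csv``   stratum-specific grip/walk thresholds
* ``flags.csv``     per-participant deficits, score and frail label
* ``table1.csv``    covariate distributions by age group and sex
* ``table2.csv``    deficit prevalence by age group and sex
* ``table3.csv``    marker-accuracy table (single + pair markers, per sex)
* ``sens_spec.png`` sensitivity/specificity summary figure (optional)
* ``manifest.json`` seed, config hash, and row counts at every stage

Re-running with the same configuration reproduces byte-identical machine
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass

import pandas as pd

from . import accuracy, descriptive, published, scoring, synthetic
from .cohort import read_cohort, write_cohort
from .config import RunConfig
from .errors import PipelineError

logger = logging.getLogger("frailtyscreen")

FLAG_CSV_COLUMNS = ["id", "E", "G", "W", "L", "P", "S", "frail"]


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    seed: int
    config_hash: int | str
    n_generated: int
    n_scored: int
    n_dropped: int
    outputs: dict


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages; abort with the stage name on any error."""
    logging.basicConfig(level=config.log_level)
    os.makedirs(config.output_dir, exist_ok=True)
    out = lambda name: os.path.join(config.output_dir, name)
    outputs: dict[str, str] = {}

    # stage 1: cohort
    try:
        if config.input_path:
            cohort = read_cohort(config.input_path)
        else:
            cohort = synthetic.generate_cohort(config.generator)
            if config.missingness_rate > 0:
                cohort = synthetic.inject_missingness(
                    cohort, config.missingness_rate, config.generator.seed + 1
                )
            write_cohort(cohort, out("cohort.csv"))
            outputs["cohort"] = out("cohort.csv")
    except Exception as exc:
        raise PipelineError(f"cohort stage failed: {exc}") from exc
    logger.info("cohort stage: %d rows", len(cohort))
    if cohort.empty:
        raise PipelineError("cohort stage produced no rows")

    # stage 2: scoring
    try:
        scoring_config = config.scoring
        if config.cutoffs_from_targets and not config.input_path:
            scoring_config = dataclass_replace_overrides(
                scoring_config, synthetic.target_cutoff_proportions(config.generator)
            )
        scored = scoring.score_and_classify(cohort, config=scoring_config)
    except Exception as exc:
        raise PipelineError(f"scoring stage failed: {exc}") from exc
    if scored.flags.empty:
        raise PipelineError(
            "scoring stage: no complete cases after dropping missing components"
        )
    logger.info(
        "scoring stage: %d in, %d complete cases, %d dropped",
        scored.n_input, len(scored.flags), scored.n_dropped,
    )
    scored.cutoffs.to_csv(out("cutoffs.csv"), index=False)
    scored.flags[FLAG_CSV_COLUMNS].to_csv(out("flags.csv"), index=False)
    outputs["cutoffs"] = out("cutoffs.csv")
    outputs["flags"] = out("flags.csv")

    # stage 3: descriptive tables
    try:
        t1 = descriptive.table1_frame(descriptive.build_table1(cohort))
        t2 = descriptive.table2_frame(descriptive.build_table2(cohort, scored.flags))
    except Exception as exc:
        raise PipelineError(f"descriptive stage failed: {exc}") from exc
    t1.to_csv(out("table1.csv"), index=False)
    t2.to_csv(out("table2.csv"), index=False)
    outputs["table1"] = out("table1.csv")
    outputs["table2"] = out("table2.csv")

    # stage 4: accuracy
    try:
        metrics = accuracy.evaluate_all_markers(
            scored.flags,
            config.wilson,
            by_sex=True,
            pair_rule=config.pair_rule,
            weighted=config.weighted_tables,
        )
        t3 = accuracy.metrics_table(metrics)
    except Exception as exc:
        raise PipelineError(f"accuracy stage failed: {exc}") from exc
    t3.to_csv(out("table3.csv"), index=False)
    outputs["table3"] = out("table3.csv")
    if config.make_figure:
        from .plotting import sens_spec_figure

        sens_spec_figure(t3, out("sens_spec.png"))
        outputs["figure"] = out("sens_spec.png")

    manifest = RunManifest(
        seed=config.generator.seed,
        config_hash=_config_hash(config),
        n_generated=int(len(cohort)),
        n_scored=int(len(scored.flags)),
        n_dropped=int(scored.n_dropped),
        outputs=outputs,
    )
    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest.__dict__, fh, indent=2, sort_keys=True)
    return manifest


def dataclass_replace_overrides(scoring_config, overrides):
    """Scoring config with grip/walk proportion overrides merged in."""
    from dataclasses import replace

    merged = dict(overrides)
    merged.update(scoring_config.proportion_overrides)
    return replace(scoring_config, proportion_overrides=merged)


def validate_against_bayes(table3: pd.DataFrame | str) -> pd.DataFrame:
    """Cross-column consistency of an accuracy table via the Bayes identities.

    For every row with defined sensitivity, specificity and prevalence,
    report |ppv - ppv_bayes(sens, spec, prev)| and the NPV analogue.  On
    internally generated tables both discrepancies are at the level of
    floating-point round-off (<= 1e-12).
    """
    if isinstance(table3, str):
        table3 = pd.read_csv(table3)
    needed = {"sensitivity", "specificity", "prevalence", "ppv", "npv"}
    if not needed <= set(table3.columns):
        raise PipelineError(
            f"malformed accuracy table: missing {sorted(needed - set(table3.columns))}"
        )
    rows = []
    for _, r in table3.iterrows():
        rec = {
            "sex": r.get("sex", ""),
            "marker": r.get("marker", ""),
            "ppv_discrepancy": float("nan"),
            "npv_discrepancy": float("nan"),
        }
        if all(pd.notna(r[k]) for k in needed):
            try:
                rec["ppv_discrepancy"] = abs(
                    r["ppv"]
                    - accuracy.ppv_from_bayes(r["sensitivity"], r["specificity"], r["prevalence"])
                )
            except ZeroDivisionError:
                pass
            try:
                rec["npv_discrepancy"] = abs(
                    r["npv"]
                    - accuracy.npv_from_bayes(r["sensitivity"], r["specificity"], r["prevalence"])
                )
            except ZeroDivisionError:
                pass
        rows.append(rec)
    report = pd.DataFrame(rows)
    report.attrs["max_discrepancy"] = float(
        report[["ppv_discrepancy", "npv_discrepancy"]].max().max()
    )
    return report


def published_bayes_check() -> pd.DataFrame:
    """Reconstruct published predictive values from published sens/spec/prev.

    Returns one row per published marker row with the Bayes-reconstructed
    PPV/NPV (percent) next to the published cells.
    """
    rows = []
    for (sex, marker), cells in published.ACCURACY_PCT.items():
        se, sp, pr = cells["sens"] / 100, cells["spec"] / 100, cells["prev"] / 100
        rows.append(
            {
                "sex": sex,
                "marker": marker,
                "ppv_published": cells["ppv"],
                "ppv_bayes": 100 * accuracy.ppv_from_bayes(se, sp, pr),
                "npv_published": cells["npv"],
                "npv_bayes": 100 * accuracy.npv_from_bayes(se, sp, pr),
            }
        )
    return pd.DataFrame(rows)
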