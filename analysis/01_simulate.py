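#!/usr/bin/env python
"""Generate the synthetic study data: reference compendium and cohorts.

Writes, under results/synthetic/:
  reference.tsv / reference_labels.tsv  - labeled log2 reference compendium
                                          (6 cell types x 4 replicates)
  mixtures.tsv / metadata.tsv           - paired lesional vs non-lesional
                                          cohort (n=20 per arm) with planted
                                          composition shifts
  severity_* and course_*               - unpaired mild/severe cohort and a
                                          3-timepoint treatment course
  true_*.tsv                            - generator ground truth
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from dermdeconv.io import write_expression_table, write_metadata
from dermdeconv.synthetic import (
    CohortArm,
    CohortConfig,
    GeneratorConfig,
    generate_cohort,
    generate_reference,
)

SEED = 20240901 % 2**31
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"

BASE = np.array([0.30, 0.15, 0.15, 0.15, 0.15, 0.10])          # non-lesional
LESIONAL_DELTA = np.array([0.20, 0.05, -0.10, -0.05, -0.05, -0.05])
SEVERE_EXTRA = np.array([0.08, 0.02, -0.04, -0.02, -0.02, -0.02])


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = GeneratorConfig(seed=SEED)
    ref, truth = generate_reference(cfg)
    write_expression_table(ref.expression, OUT / "reference.tsv")
    pd.DataFrame(
        {"sample_id": list(ref.cell_type_of), "cell_type": list(ref.cell_type_of.values())}
    ).to_csv(OUT / "reference_labels.tsv", sep="\t", index=False)
    truth.signature.to_csv(OUT / "true_signature.tsv", sep="\t",
                           float_format="%.12g", index_label="probe_id")

    # paired lesional vs non-lesional cohort with planted shifts
    paired = CohortConfig(
        arms=[
            CohortArm("lesional", BASE + LESIONAL_DELTA, 20),
            CohortArm("non_lesional", BASE, 20, lesional="non_lesional"),
        ],
        seed=SEED + 1,
    )
    expr, md, gt = generate_cohort(truth.signature, paired)
    write_expression_table(expr, OUT / "mixtures.tsv")
    write_metadata(md, OUT / "metadata.tsv")
    gt.fractions.to_csv(OUT / "true_fractions.tsv", sep="\t",
                        float_format="%.12g", index_label="sample_id")

    # unpaired mild vs severe cohort
    severity = CohortConfig(
        arms=[
            CohortArm("mild", BASE + LESIONAL_DELTA, 14, severity="mild"),
            CohortArm("severe", BASE + LESIONAL_DELTA + SEVERE_EXTRA, 13, severity="severe"),
        ],
        paired=False,
        seed=SEED + 2,
    )
    expr_s, md_s, gt_s = generate_cohort(truth.signature, severity)
    write_expression_table(expr_s, OUT / "severity_mixtures.tsv")
    write_metadata(md_s, OUT / "severity_metadata.tsv")
    gt_s.fractions.to_csv(OUT / "severity_true_fractions.tsv", sep="\t",
                          float_format="%.12g", index_label="sample_id")

    # treatment course: lesional composition relaxing back to non-lesional
    course_arms = []
    for t, w in enumerate([1.0, 0.5, 0.0]):  # before, during, after treatment
        course_arms.append(
            CohortArm(f"week{t * 6}", BASE + w * LESIONAL_DELTA, 12, timepoint=float(t))
        )
    course = CohortConfig(arms=course_arms, seed=SEED + 3)
    expr_c, md_c, gt_c = generate_cohort(truth.signature, course)
    write_expression_table(expr_c, OUT / "course_mixtures.tsv")
    write_metadata(md_c, OUT / "course_metadata.tsv")
    gt_c.fractions.to_csv(OUT / "course_true_fractions.tsv", sep="\t",
                          float_format="%.12g", index_label="sample_id")

    summary = {
        "seed": SEED,
        "cell_types": cfg.cell_types,
        "non_lesional_composition": BASE.tolist(),
        "lesional_delta_pp": (LESIONAL_DELTA * 100).tolist(),
        "severe_extra_pp": (SEVERE_EXTRA * 100).tolist(),
        "n_reference_samples": len(ref.expression.sample_ids),
        "cohort_sizes": {"paired": 40, "severity": 27, "course": 36},
    }
    (OUT / "simulation_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"reference: {ref.expression.shape[0]} probes x {ref.expression.shape[1]} samples, "
          f"{len(cfg.cell_types)} cell types")
    print(f"cohorts written to {OUT} (paired n=40, severity n=27, course n=36)")
    shifts = {ct: float(d) for ct, d in zip(cfg.cell_types, (LESIONAL_DELTA * 100).round(1))}
    print(f"planted lesional shifts (pp): {shifts}")


if __name__ == "__main__":
    main()
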