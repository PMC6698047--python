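#!/usr/bin/env python
"""Validate the deconvolution the way one would without real ground truth.

Four checks, mirroring how signature matrices are benchmarked in practice:
isolated-cell-type assignment on the same and on a simulated second
platform; comparison of cohort means to an external-style benchmark table
(here built from generator truth, standing in for literature flow-cytometry
values); lesional / non-lesional ratios of means (the immunohistochemistry-
style comparison); and inter-study variability across replicate synthetic
studies. Writes tables under results/validation/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from dermdeconv.deconvolution import deconvolve
from dermdeconv.io import ExpressionMatrix, read_expression_table, read_metadata, read_signature_table
from dermdeconv.synthetic import CohortArm, CohortConfig, generate_cohort, simulate_platform_shift
from dermdeconv.validation import (
    assignment_matrix,
    compare_to_benchmark,
    interstudy_variability,
    ratio_of_means,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20240904 % 2**31


def main() -> None:
    out = ROOT / "validation"
    out.mkdir(parents=True, exist_ok=True)
    sig = read_signature_table(ROOT / "signature.tsv")
    truth_sig = pd.read_csv(ROOT / "synthetic" / "true_signature.tsv", sep="\t", index_col=0)

    # 1. isolated-cell-type assignment, same platform and after platform shift
    self_res = deconvolve(ExpressionMatrix(sig.data.copy(), "linear"), sig)
    labels = pd.Series(sig.cell_types, index=sig.cell_types)
    mat, dom_self = assignment_matrix(self_res.fractions, labels)
    shifted = simulate_platform_shift(ExpressionMatrix(truth_sig, "linear"), seed=SEED)
    shift_res = deconvolve(shifted, sig)
    mat_shift, dom_shift = assignment_matrix(
        shift_res.fractions, pd.Series(truth_sig.columns, index=truth_sig.columns)
    )
    mat.to_csv(out / "assignment_same_platform.tsv", sep="\t",
               float_format="%.6g", index_label="true_type")
    mat_shift.to_csv(out / "assignment_shifted_platform.tsv", sep="\t",
                     float_format="%.6g", index_label="true_type")
    print(f"isolated-type diagonal dominance: same platform {dom_self:.2f}, "
          f"after simulated platform shift {dom_shift:.2f}")

    # 2. benchmark comparison: external-style table from generator truth
    fractions = pd.read_csv(ROOT / "fractions" / "paired.tsv", sep="\t", index_col=0)
    metadata = read_metadata(ROOT / "synthetic" / "metadata.tsv")
    true_frac = pd.read_csv(ROOT / "synthetic" / "true_fractions.tsv", sep="\t", index_col=0)
    rows = []
    for arm, idx in metadata.groupby("arm").groups.items():
        block = true_frac.loc[idx]
        for ct in true_frac.columns:
            rows.append({"cell_type": ct, "phenotype": arm,
                         "mean_fraction": block[ct].mean(),
                         "se": block[ct].std(ddof=1) / np.sqrt(len(block)),
                         "n": len(block), "source": "synthetic ground truth"})
    benchmark = pd.DataFrame(rows)
    benchmark.to_csv(out / "benchmark_table.synthetic.tsv", sep="\t", index=False,
                     float_format="%.6g")
    matched, _ = compare_to_benchmark(fractions, metadata, benchmark, "arm")
    matched.to_csv(out / "benchmark_comparison.tsv", sep="\t", index=False,
                   float_format="%.6g")
    within = (matched["difference"].abs()
              <= 2 * np.hypot(matched["estimated_se"], matched["benchmark_se"])).mean()
    print(f"benchmark comparison: {len(matched)} (type, arm) rows, "
          f"{within:.0%} within 2 combined SE of the benchmark")

    # 3. lesional / non-lesional ratio of mean fractions per cell type
    ratios = {ct: ratio_of_means(fractions, metadata, ct, "arm", "lesional", "non_lesional")
              for ct in fractions.columns}
    true_ratios = {ct: ratio_of_means(true_frac, metadata, ct, "arm", "lesional", "non_lesional")
                   for ct in fractions.columns}
    pd.DataFrame({"estimated_ratio": ratios, "true_ratio": true_ratios}).to_csv(
        out / "lesional_ratios.tsv", sep="\t", float_format="%.4g", index_label="cell_type")
    worst = max(abs(np.log(ratios[ct] / true_ratios[ct])) for ct in ratios)
    print(f"lesional/non-lesional ratios of means: max |log ratio error| {worst:.3f}")

    # 4. inter-study variability: three replicate studies of one population
    rng = np.random.default_rng(SEED)
    base = np.array([0.30, 0.15, 0.15, 0.15, 0.15, 0.10])
    frames, metas = [], []
    for study in ["studyA", "studyB", "studyC"]:
        cc = CohortConfig(
            arms=[CohortArm(f"{study}_h", base, 12, disease="healthy",
                            lesional="not_applicable", study_id=study)],
            paired=False, seed=int(rng.integers(2**31 - 1)),
        )
        expr, md, _ = generate_cohort(truth_sig, cc)
        frames.append(deconvolve(expr, sig).fractions)
        metas.append(md)
    all_frac = pd.concat(frames)
    all_md = pd.concat(metas)
    per_study, spread = interstudy_variability(all_frac, all_md)
    per_study.to_csv(out / "interstudy_per_study.tsv", sep="\t", index=False,
                     float_format="%.6g")
    spread.to_csv(out / "interstudy_spread.tsv", sep="\t", index=False, float_format="%.6g")
    print(f"inter-study variability over 3 replicate studies: "
          f"between-study SD of study means {spread['between_study_sd'].max():.4f} max, "
          f"{spread['between_study_sd'].mean():.4f} mean")


if __name__ == "__main__":
    main()
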