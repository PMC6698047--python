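"""Verification strategies for skin deconvolution results.

Four complementary checks mirror how reference-based deconvolution is
typically validated when no ground truth exists for the real cohorts:

* comparison of estimated mean fractions against an external benchmark
  table (e.g. flow-cytometry literature values);
* ratios of stratum-mean fractions (e.g. lesional / non-lesional), which
  are comparable to immunohistochemistry count ratios even though absolute
  per-area counts are not;
* an assignment matrix for samples of known isolated cell types, summarized
  by diagonal dominance (how often the own-type estimate is the largest);
* inter-study variability of per-(study, phenotype) mean fractions.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

BENCHMARK_COLUMNS = ["cell_type", "phenotype", "mean_fraction", "se", "n", "source"]


def read_benchmark_table(path: str | Path) -> pd.DataFrame:
    """Read an external benchmark TSV (cell type, phenotype, mean, SE, n, source)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(BENCHMARK_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"benchmark table missing columns: {sorted(missing)}")
    if ((df["mean_fraction"] < 0) | (df["mean_fraction"] > 1)).any():
        raise ValueError("benchmark mean_fraction must lie in [0, 1]")
    return df


def read_alias_map(path: str | Path) -> dict[str, str]:
    """Marker/name alias -> signature cell-type name (e.g. CD11c -> mDC)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def compare_to_benchmark(
    fractions: pd.DataFrame,
    metadata: pd.DataFrame,
    benchmark: pd.DataFrame,
    phenotype_key: str,
    alias_map: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Estimated mean +/- SE vs benchmark mean +/- SE per (cell type, phenotype).

    Benchmark cell-type names are first translated through ``alias_map``.
    Returns (matched comparison table, unmatched benchmark rows).
    """
    alias_map = alias_map or {}
    md = metadata.loc[fractions.index]
    matched, unmatched = [], []
    for _, row in benchmark.iterrows():
        ct = alias_map.get(row["cell_type"], row["cell_type"])
        pheno = row["phenotype"]
        sel = fractions.loc[md[md[phenotype_key] == pheno].index]
        if ct not in fractions.columns or sel.empty:
            unmatched.append(row)
            continue
        v = sel[ct].to_numpy(float)
        n = v.size
        se = float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        matched.append(
            {
                "cell_type": ct,
                "phenotype": pheno,
                "estimated_mean": float(v.mean()),
                "estimated_se": se,
                "estimated_n": n,
                "benchmark_mean": float(row["mean_fraction"]),
                "benchmark_se": float(row["se"]) if pd.notna(row.get("se")) else np.nan,
                "difference": float(v.mean()) - float(row["mean_fraction"]),
                "source": row.get("source", ""),
            }
        )
    if not matched:
        raise ValueError("no benchmark row matched the estimates")
    return pd.DataFrame(matched), pd.DataFrame(unmatched)


def ratio_of_means(
    fractions: pd.DataFrame,
    metadata: pd.DataFrame,
    cell_type: str,
    stratum_key: str,
    numerator_stratum: str,
    denominator_stratum: str,
) -> float:
    """Ratio of stratum-mean fractions (ratio of averages, not average of ratios)."""
    md = metadata.loc[fractions.index]
    num = fractions.loc[md[md[stratum_key] == numerator_stratum].index, cell_type]
    den = fractions.loc[md[md[stratum_key] == denominator_stratum].index, cell_type]
    if num.empty or den.empty:
        raise ValueError("both strata must be non-empty")
    den_mean = float(den.mean())
    if den_mean <= 0:
        raise ValueError("denominator stratum mean is zero")
    return float(num.mean()) / den_mean


def assignment_matrix(
    fractions: pd.DataFrame, true_labels: pd.Series
) -> tuple[pd.DataFrame, float]:
    """Mean estimated fraction vector per true isolated cell type.

    Rows are true labels, columns estimated cell types. ``diagonal_dominance``
    is the share of in-signature true labels whose own-type mean estimate is
    the row maximum. Out-of-signature labels contribute rows but not to the
    dominance score.
    """
    labels = true_labels.loc[fractions.index]
    mat = fractions.groupby(labels).mean()
    in_sig = [lab for lab in mat.index if lab in fractions.columns]
    if in_sig:
        hits = sum(1 for lab in in_sig if mat.loc[lab].idxmax() == lab)
        dominance = hits / len(in_sig)
    else:
        dominance = np.nan
    return mat, float(dominance)


def interstudy_variability(
    fractions: pd.DataFrame,
    metadata: pd.DataFrame,
    study_key: str = "study_id",
    phenotype_key: str = "disease",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(study, phenotype, cell type) mean +/- SD, and between-study spread.

    Returns the long per-study table and a per-(phenotype, cell type) table
    with the SD of study means plus the maximally deviating study.
    """
    md = metadata.loc[fractions.index]
    if md[study_key].nunique() < 2:
        raise ValueError("need at least two studies")
    rows = []
    for (study, pheno), idx in fractions.groupby([md[study_key], md[phenotype_key]]).groups.items():
        block = fractions.loc[idx]
        for ct in fractions.columns:
            v = block[ct].to_numpy(float)
            rows.append(
                {
                    "study": study,
                    "phenotype": pheno,
                    "cell_type": ct,
                    "mean": float(v.mean()),
                    "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                    "n": v.size,
                }
            )
    per_study = pd.DataFrame(rows).sort_values(["phenotype", "cell_type", "study"], ignore_index=True)
    spread_rows = []
    for (pheno, ct), grp in per_study.groupby(["phenotype", "cell_type"]):
        means = grp.set_index("study")["mean"]
        grand = means.mean()
        spread_rows.append(
            {
                "phenotype": pheno,
                "cell_type": ct,
                "between_study_sd": float(means.std(ddof=1)) if len(means) > 1 else 0.0,
                "max_deviation_study": (means - grand).abs().idxmax(),
            }
        )
    return per_study, pd.DataFrame(spread_rows)
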