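"""Rank-based group comparisons for compositional cell-type fractions.

Fractions are bounded in [0, 1] and typically skewed, so inference uses
non-parametric Wilcoxon tests: the signed-rank test for within-subject
(paired) contrasts such as lesional vs non-lesional skin, and the rank-sum
test for independent groups such as diseased vs healthy. Multiple testing
across the cell types of one contrast is controlled by Benjamini-Hochberg.

Conventions (fixed so results are deterministic and documented):

* paired: zero differences are dropped before ranking; exact p for n <= 25
  pairs with untied |differences|, normal approximation with continuity
  correction otherwise;
* unpaired: exact p when min(n_a, n_b) <= 10 and no cross-group ties,
  normal approximation with tie correction and continuity otherwise;
* all tests two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

EXACT_PAIRED_MAX_N = 25
EXACT_RANKSUM_MAX_N = 10


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def signed_rank_test(diffs: np.ndarray) -> tuple[float, float, int]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Returns (statistic, p, n_dropped_zeros). All-zero differences give p = 1.
    """
    diffs = np.asarray(diffs, dtype=float)
    nonzero = diffs[diffs != 0]
    n_dropped = diffs.size - nonzero.size
    if nonzero.size == 0:
        return 0.0, 1.0, n_dropped
    ranks_tied = len(np.unique(np.abs(nonzero))) < nonzero.size
    if nonzero.size <= EXACT_PAIRED_MAX_N and not ranks_tied:
        method = "exact"
    else:
        method = "approx"
    res = sps.wilcoxon(
        nonzero, zero_method="wilcox", alternative="two-sided",
        correction=(method == "approx"), method=method,
    )
    return float(res.statistic), float(min(res.pvalue, 1.0)), n_dropped


def rank_sum_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    if min(a.size, b.size) <= EXACT_RANKSUM_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=(method == "asymptotic"))
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _direction(delta: float) -> int:
    return int(np.sign(delta))


def paired_compare(
    fractions: pd.DataFrame,
    metadata: pd.DataFrame,
    condition_key: str,
    condition_a: str,
    condition_b: str,
    pair_key: str = "subject_id",
    bh: bool = True,
) -> pd.DataFrame:
    """Wilcoxon signed-rank test per cell type for a paired contrast.

    Samples are matched on ``pair_key``; subjects missing either arm are
    dropped. Direction is the sign of the median paired difference (a - b).
    """
    md = metadata.loc[fractions.index]
    arm_a = md[md[condition_key] == condition_a]
    arm_b = md[md[condition_key] == condition_b]
    subjects = sorted(set(arm_a[pair_key]) & set(arm_b[pair_key]) - {np.nan})
    if not subjects:
        raise ValueError("no complete pairs for the requested contrast")
    # one sample per subject per arm (first occurrence if replicated)
    idx_a = [arm_a[arm_a[pair_key] == s].index[0] for s in subjects]
    idx_b = [arm_b[arm_b[pair_key] == s].index[0] for s in subjects]
    rows = []
    for ct in fractions.columns:
        diffs = fractions.loc[idx_a, ct].to_numpy() - fractions.loc[idx_b, ct].to_numpy()
        stat, p, n_dropped = signed_rank_test(diffs)
        rows.append(
            {
                "cell_type": ct,
                "contrast": f"{condition_a} vs {condition_b} (paired)",
                "test": "signed_rank",
                "statistic": stat,
                "p_value": p,
                "n_a": len(idx_a),
                "n_b": len(idx_b),
                "n_dropped_zeros": n_dropped,
                "direction": _direction(float(np.median(diffs))),
            }
        )
    out = pd.DataFrame(rows)
    if bh:
        out["q_value"] = adjust_bh(out["p_value"].to_numpy())
    return out


def unpaired_compare(
    fractions: pd.DataFrame,
    metadata: pd.DataFrame,
    group_key: str,
    group_a: str,
    group_b: str,
    bh: bool = True,
) -> pd.DataFrame:
    """Wilcoxon rank-sum test per cell type for an independent-groups contrast."""
    md = metadata.loc[fractions.index]
    a_idx = md[md[group_key] == group_a].index
    b_idx = md[md[group_key] == group_b].index
    if len(a_idx) == 0 or len(b_idx) == 0:
        raise ValueError("both groups must contain at least one sample")
    rows = []
    for ct in fractions.columns:
        a = fractions.loc[a_idx, ct].to_numpy()
        b = fractions.loc[b_idx, ct].to_numpy()
        stat, p = rank_sum_test(a, b)
        rows.append(
            {
                "cell_type": ct,
                "contrast": f"{group_a} vs {group_b}",
                "test": "rank_sum",
                "statistic": stat,
                "p_value": p,
                "n_a": len(a),
                "n_b": len(b),
                "direction": _direction(float(np.median(a) - np.median(b))),
            }
        )
    out = pd.DataFrame(rows)
    if bh:
        out["q_value"] = adjust_bh(out["p_value"].to_numpy())
    return out


def treatment_course(
    fractions: pd.DataFrame,
    metadata: pd.DataFrame,
    subject_key: str = "subject_id",
    timepoint_key: str = "timepoint",
    timepoints: list | None = None,
) -> pd.DataFrame:
    """Paired contrasts between consecutive timepoints of a treatment series.

    For each consecutive timepoint pair and cell type: the mean per-subject
    difference and fold change (later / earlier of subject means) plus a
    signed-rank p-value across subjects observed at both timepoints.
    """
    md = metadata.loc[fractions.index]
    if timepoints is None:
        timepoints = sorted(md[timepoint_key].dropna().unique())
    if len(timepoints) < 2:
        raise ValueError("need at least two timepoints")
    rows = []
    any_pairs = False
    for t0, t1 in zip(timepoints[:-1], timepoints[1:]):
        arm0 = md[md[timepoint_key] == t0]
        arm1 = md[md[timepoint_key] == t1]
        subjects = sorted(set(arm0[subject_key]) & set(arm1[subject_key]))
        if not subjects:
            continue
        any_pairs = True
        idx0 = [arm0[arm0[subject_key] == s].index[0] for s in subjects]
        idx1 = [arm1[arm1[subject_key] == s].index[0] for s in subjects]
        for ct in fractions.columns:
            v0 = fractions.loc[idx0, ct].to_numpy()
            v1 = fractions.loc[idx1, ct].to_numpy()
            stat, p, _ = signed_rank_test(v1 - v0)
            mean0 = float(v0.mean())
            rows.append(
                {
                    "cell_type": ct,
                    "timepoint_from": t0,
                    "timepoint_to": t1,
                    "n_pairs": len(subjects),
                    "mean_difference": float((v1 - v0).mean()),
                    "fold_change": float(v1.mean() / mean0) if mean0 > 0 else np.nan,
                    "statistic": stat,
                    "p_value": p,
                }
            )
    if not any_pairs:
        raise ValueError("no subjects observed at consecutive timepoints")
    return pd.DataFrame(rows)
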