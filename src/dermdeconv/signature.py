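"""Signature-matrix construction from a labeled reference compendium.

The builder follows the classical three-step marker selection used for
reference-based deconvolution of microarray data:

1. one-vs-rest differential testing per probe and cell type (two-sided
   unequal-variance t-test, Benjamini-Hochberg q < 0.3 within each cell
   type's family of probes);
2. ranking of the surviving candidates by log2 fold change (mean in the cell
   type minus mean over all other reference samples);
3. for each candidate marker count G in a configured range, forming the
   union of the top-G probes per cell type and keeping the G whose probe x
   cell-type matrix of mean linear intensities minimizes the 2-norm
   condition number kappa = sigma_max / sigma_min.

Testing and ranking operate on log2 intensities; the stored signature holds
linear-scale per-type means, because the downstream mixture model is linear
in transcript abundance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, SignatureMatrix, to_linear

logger = logging.getLogger(__name__)


@dataclass
class ReferenceDataset:
    """Labeled reference compendium: expression plus a cell type per sample."""

    expression: ExpressionMatrix
    cell_type_of: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(self.cell_type_of) - set(self.expression.sample_ids)
        if missing:
            raise ValueError(f"labels for unknown samples: {sorted(missing)[:5]}")
        unlabeled = set(self.expression.sample_ids) - set(self.cell_type_of)
        if unlabeled:
            raise ValueError(f"unlabeled samples: {sorted(unlabeled)[:5]}")
        if len(set(self.cell_type_of.values())) < 2:
            raise ValueError("reference needs at least 2 distinct cell types")

    @property
    def cell_types(self) -> list[str]:
        seen: list[str] = []
        for s in self.expression.sample_ids:
            ct = self.cell_type_of[s]
            if ct not in seen:
                seen.append(ct)
        return seen

    def samples_of(self, cell_type: str) -> list[str]:
        return [s for s in self.expression.sample_ids if self.cell_type_of[s] == cell_type]


def differential_probes(
    ref: ReferenceDataset, q_threshold: float = 0.3
) -> pd.DataFrame:
    """One-vs-rest Welch t-tests per probe and cell type.

    Returns a frame with columns ``probe_id, cell_type, t_statistic, p_value,
    q_value, log2_fold_change`` restricted to records with BH q below
    ``q_threshold``. Expression must be on log2 scale. Probes with zero
    variance in both arms are excluded (the t statistic is undefined there).
    """
    expr = ref.expression
    if expr.scale != "log2":
        raise ValueError("differential testing requires log2-scale expression")
    records = []
    values = expr.data
    for ct in ref.cell_types:
        in_samples = ref.samples_of(ct)
        if len(in_samples) < 2:
            raise ValueError(f"cell type {ct!r} has fewer than 2 reference samples")
        out_samples = [s for s in expr.sample_ids if s not in set(in_samples)]
        if len(out_samples) < 2:
            raise ValueError(f"fewer than 2 rest samples for cell type {ct!r}")
        a = values[in_samples].to_numpy()
        b = values[out_samples].to_numpy()
        # both-arm zero variance -> t undefined; drop deterministically
        defined = ~((a.std(axis=1) == 0) & (b.std(axis=1) == 0))
        if not defined.any():
            continue
        t, p = sps.ttest_ind(a[defined], b[defined], axis=1, equal_var=False)
        q = multipletests(p, method="fdr_bh")[1]
        lfc = a[defined].mean(axis=1) - b[defined].mean(axis=1)
        probes = values.index.to_numpy()[defined]
        keep = q < q_threshold
        for pid, ti, pi, qi, fi in zip(
            probes[keep], t[keep], p[keep], q[keep], lfc[keep]
        ):
            records.append((pid, ct, float(ti), float(pi), float(qi), float(fi)))
    return pd.DataFrame(
        records,
        columns=["probe_id", "cell_type", "t_statistic", "p_value", "q_value", "log2_fold_change"],
    )


def rank_candidates(stats: pd.DataFrame, cell_type: str) -> list[str]:
    """Candidate probes for one cell type, descending by log2 fold change.

    Ties break lexicographically by probe id so the ordering is deterministic.
    """
    sub = stats[stats["cell_type"] == cell_type]
    if sub.empty:
        return []
    ordered = sub.sort_values(
        ["log2_fold_change", "probe_id"], ascending=[False, True], kind="mergesort"
    )
    return ordered["probe_id"].tolist()


def condition_number(matrix: np.ndarray | pd.DataFrame) -> float:
    """2-norm condition number sigma_max / sigma_min; +inf if rank deficient."""
    arr = np.asarray(matrix, dtype=float)
    if arr.shape[0] < arr.shape[1]:
        return float("inf")
    s = np.linalg.svd(arr, compute_uv=False)
    if s.size == 0 or s[-1] <= s[0] * 1e-12 or s[0] == 0:
        return float("inf")
    return float(s[0] / s[-1])


def _type_mean_linear(ref: ReferenceDataset) -> pd.DataFrame:
    """Per-cell-type mean linear intensity for every probe (probes x types)."""
    linear = to_linear(ref.expression).data
    cols = {ct: linear[ref.samples_of(ct)].mean(axis=1) for ct in ref.cell_types}
    return pd.DataFrame(cols)[ref.cell_types]


def _union_topg(candidates: dict[str, list[str]], g: int, probe_order: pd.Index) -> list[str]:
    chosen: set[str] = set()
    for ct, ranked in candidates.items():
        chosen.update(ranked[: min(g, len(ranked))])
    # stable probe order as in the reference matrix
    return [p for p in probe_order if p in chosen]


def build_signature(
    ref: ReferenceDataset,
    g_min: int = 50,
    g_max: int = 150,
    q_threshold: float = 0.3,
) -> SignatureMatrix:
    """Build the signature matrix with condition-number-minimizing G.

    For every integer G in ``[g_min, g_max]`` the top min(G, available)
    ranked candidates per cell type are pooled (union; shared probes counted
    once), the probe x cell-type matrix of mean linear intensities is formed,
    and its condition number computed. The G achieving minimal kappa wins,
    smallest G on ties. Errors if any cell type retains no candidate after
    the differential filter.
    """
    if g_min > g_max or g_min < 1:
        raise ValueError("need 1 <= g_min <= g_max")
    stats = differential_probes(ref, q_threshold=q_threshold)
    candidates = {ct: rank_candidates(stats, ct) for ct in ref.cell_types}
    empty = [ct for ct, lst in candidates.items() if not lst]
    if empty:
        raise ValueError(f"no candidate probes for cell types: {empty}")
    type_means = _type_mean_linear(ref)
    probe_order = ref.expression.data.index

    best_g: int | None = None
    best_kappa = float("inf")
    best_probes: list[str] = []
    for g in range(g_min, g_max + 1):
        probes = _union_topg(candidates, g, probe_order)
        kappa = condition_number(type_means.loc[probes])
        if kappa < best_kappa:
            best_g, best_kappa, best_probes = g, kappa, probes
    if best_g is None or not np.isfinite(best_kappa):
        # all G rank deficient (e.g. duplicated cell types in the reference)
        logger.warning("signature rank-deficient for every G in [%d, %d]", g_min, g_max)
        g0 = g_min
        probes0 = _union_topg(candidates, g0, probe_order)
        return SignatureMatrix(
            type_means.loc[probes0],
            G=g0,
            condition_number=float("inf"),
            provenance=_provenance(ref, g_min, g_max, q_threshold, candidates, degenerate=True),
        )
    return SignatureMatrix(
        type_means.loc[best_probes],
        G=best_g,
        condition_number=best_kappa,
        provenance=_provenance(ref, g_min, g_max, q_threshold, candidates),
    )


def _provenance(ref, g_min, g_max, q_threshold, candidates, degenerate=False) -> dict:
    return {
        "g_min": g_min,
        "g_max": g_max,
        "q_threshold": q_threshold,
        "n_reference_samples": len(ref.expression.sample_ids),
        "n_cell_types": len(ref.cell_types),
        "candidate_counts": {ct: len(lst) for ct, lst in candidates.items()},
        "condition_number_on": "raw linear-scale signature values",
        "degenerate": degenerate,
    }
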