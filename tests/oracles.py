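"""Independent brute-force oracles used to check the package's results.

Everything here is written as direct loops / closed forms from first
principles, deliberately not sharing code paths with dermdeconv.
"""

from __future__ import annotations

import math
from itertools import combinations, product

import numpy as np


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided unequal-variance t-test from the closed form."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    from scipy.stats import t as tdist  # distribution function only

    p = 2 * tdist.sf(abs(t), df)
    return t, p


def bh_stepup(p_values) -> np.ndarray:
    """Benjamini-Hochberg q-values via the explicit step-up definition."""
    p = np.asarray(p_values, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        q[i] = running_min
    return q


def brute_force_signature_search(
    expr_log2: "pd.DataFrame",
    labels: dict[str, str],
    g_min: int,
    g_max: int,
    q_threshold: float = 0.3,
) -> tuple[int, list[str], float]:
    """Exhaustive G-search re-done from scratch.

    Returns (best G, sorted probe union, kappa). Per-type one-vs-rest Welch
    tests, per-type BH, fold-change ranking with lexicographic tie-break,
    union of top-G per type, condition number by direct SVD; smallest G wins
    ties.
    """
    import pandas as pd

    samples = list(expr_log2.columns)
    types = []
    for s in samples:
        if labels[s] not in types:
            types.append(labels[s])
    candidates: dict[str, list[str]] = {}
    for ct in types:
        in_cols = [s for s in samples if labels[s] == ct]
        out_cols = [s for s in samples if labels[s] != ct]
        rows = []
        for probe in expr_log2.index:
            a = expr_log2.loc[probe, in_cols].to_numpy(float)
            b = expr_log2.loc[probe, out_cols].to_numpy(float)
            if a.std() == 0 and b.std() == 0:
                continue
            _, p = welch_t(a, b)
            rows.append((probe, p, a.mean() - b.mean()))
        q = bh_stepup([r[1] for r in rows])
        kept = [(r[0], r[2]) for r, qi in zip(rows, q) if qi < q_threshold]
        kept.sort(key=lambda x: (-x[1], x[0]))
        candidates[ct] = [probe for probe, _ in kept]

    linear = 2.0 ** expr_log2
    type_means = pd.DataFrame(
        {ct: linear[[s for s in samples if labels[s] == ct]].mean(axis=1) for ct in types}
    )[types]

    best = None
    for g in range(g_min, g_max + 1):
        union: set[str] = set()
        for ct in types:
            union.update(candidates[ct][:g])
        probes = [p for p in expr_log2.index if p in union]
        mat = type_means.loc[probes].to_numpy()
        if mat.shape[0] < mat.shape[1]:
            kappa = float("inf")
        else:
            s = np.linalg.svd(mat, compute_uv=False)
            kappa = float("inf") if s[-1] <= s[0] * 1e-12 else float(s[0] / s[-1])
        if best is None or kappa < best[2]:
            best = (g, sorted(probes), kappa)
    return best


def signed_rank_exact_p(diffs) -> float:
    """Two-sided exact signed-rank p by enumerating all sign assignments."""
    d = np.asarray([x for x in diffs if x != 0], float)
    n = len(d)
    if n == 0:
        return 1.0
    ranks = _rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    total = ranks.sum()
    # two-sided: distance of W+ from its mean under the null
    center = total / 2.0
    observed = abs(w_plus - center)
    count = 0
    for signs in product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - center) >= observed - 1e-12:
            count += 1
    return count / 2**n


def rank_sum_exact_p(a, b) -> float:
    """Two-sided exact rank-sum p by enumerating all rank subsets."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    ranks = _rankdata(pooled)
    na = len(a)
    w_obs = ranks[:na].sum()
    center = na * (len(pooled) + 1) / 2.0
    observed = abs(w_obs - center)
    count = 0
    total = 0
    for subset in combinations(range(len(pooled)), na):
        w = sum(ranks[i] for i in subset)
        total += 1
        if abs(w - center) >= observed - 1e-12:
            count += 1
    return count / total


def _rankdata(x: np.ndarray) -> np.ndarray:
    """Average ranks (midranks for ties), written out explicitly."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks
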