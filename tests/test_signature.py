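import numpy as np
import pandas as pd
import pytest

from dermdeconv.io import ExpressionMatrix
from dermdeconv.signature import (
    ReferenceDataset,
    build_signature,
    condition_number,
    differential_probes,
    rank_candidates,
)

from conftest import make_reference
from oracles import bh_stepup, brute_force_signature_search, welch_t


def reference_with_planted_probe(seed=0):
    """Probe P ~ N(10, 0.1) in type A (4 reps), N(4, 0.1) elsewhere (12 reps)."""
    rng = np.random.default_rng(seed)
    n_probes, probes = 30, [f"p{i}" for i in range(30)]
    cols, labels = {}, {}
    for ct, reps in [("A", 4), ("B", 6), ("C", 6)]:
        for r in range(reps):
            sid = f"{ct}{r}"
            base = rng.normal(6.0, 0.5, n_probes)
            base[0] = rng.normal(10.0 if ct == "A" else 4.0, 0.1)
            cols[sid] = base
            labels[sid] = ct
    return ReferenceDataset(ExpressionMatrix(pd.DataFrame(cols, index=probes), "log2"), labels)


class TestDifferentialProbes:
    def test_planted_marker_detected_with_expected_fold_change(self):
        ref = reference_with_planted_probe()
        stats = differential_probes(ref, q_threshold=0.3)
        hit = stats[(stats["probe_id"] == "p0") & (stats["cell_type"] == "A")]
        assert len(hit) == 1
        assert hit["q_value"].iloc[0] < 0.3
        assert hit["log2_fold_change"].iloc[0] == pytest.approx(6.0, abs=0.3)

    def test_welch_t_and_bh_match_brute_force(self):
        ref = reference_with_planted_probe(seed=1)
        stats = differential_probes(ref, q_threshold=1.0)  # keep everything testable
        expr = ref.expression.data
        sub = stats[stats["cell_type"] == "A"].set_index("probe_id")
        in_cols = ref.samples_of("A")
        out_cols = [s for s in expr.columns if s not in in_cols]
        ps = {}
        for probe in expr.index:
            t, p = welch_t(expr.loc[probe, in_cols], expr.loc[probe, out_cols])
            ps[probe] = p
            if probe in sub.index:
                assert sub.loc[probe, "t_statistic"] == pytest.approx(t, rel=1e-9)
                assert sub.loc[probe, "p_value"] == pytest.approx(p, rel=1e-9)
        q_oracle = bh_stepup([ps[p] for p in expr.index])
        for probe, q in zip(expr.index, q_oracle):
            if probe in sub.index:
                assert sub.loc[probe, "q_value"] == pytest.approx(q, rel=1e-9)

    def test_q_value_never_below_p_value(self):
        ref = reference_with_planted_probe(seed=2)
        stats = differential_probes(ref, q_threshold=1.0)
        assert (stats["q_value"] >= stats["p_value"] - 1e-12).all()

    def test_zero_variance_probe_excluded(self):
        ref = reference_with_planted_probe()
        data = ref.expression.data.copy()
        data.loc["p5"] = 7.0  # constant everywhere
        ref2 = ReferenceDataset(ExpressionMatrix(data, "log2"), ref.cell_type_of)
        stats = differential_probes(ref2, q_threshold=1.0)
        assert "p5" not in set(stats["probe_id"])

    def test_zero_threshold_gives_empty_result(self):
        ref = reference_with_planted_probe()
        assert differential_probes(ref, q_threshold=0.0).empty

    def test_cell_type_with_single_sample_is_error(self):
        ref = reference_with_planted_probe()
        labels = dict(ref.cell_type_of)
        labels["A0"] = "D"  # orphan type with one sample
        ref2 = ReferenceDataset(ref.expression, labels)
        with pytest.raises(ValueError, match="D"):
            differential_probes(ref2)

    def test_candidate_lists_monotone_in_q_threshold(self):
        ref, _ = make_reference(seed=3)
        loose = differential_probes(ref, q_threshold=0.5)
        tight = differential_probes(ref, q_threshold=0.1)
        for ct in {v for v in ref.cell_type_of.values()}:
            assert set(rank_candidates(tight, ct)) <= set(rank_candidates(loose, ct))


class TestRankCandidates:
    def test_descending_by_fold_change_with_lexicographic_ties(self):
        stats = pd.DataFrame(
            {
                "probe_id": ["pz", "pa", "pb", "pc"],
                "cell_type": ["A"] * 4,
                "t_statistic": [1.0] * 4,
                "p_value": [0.01] * 4,
                "q_value": [0.02] * 4,
                "log2_fold_change": [2.0, 5.0, 3.0, 5.0],
            }
        )
        assert rank_candidates(stats, "A") == ["pa", "pc", "pb", "pz"]

    def test_empty_candidate_set(self):
        stats = pd.DataFrame(columns=["probe_id", "cell_type", "log2_fold_change"])
        assert rank_candidates(stats, "A") == []


class TestConditionNumber:
    def test_orthonormal_columns_give_kappa_one(self):
        assert condition_number(np.eye(4)[:, :2]) == pytest.approx(1.0)

    def test_diag_1_2_matches_svd_oracle(self):
        mat = np.array([[1.0, 0.0], [0.0, 2.0]])
        s = np.linalg.svd(mat, compute_uv=False)
        assert condition_number(mat) == pytest.approx(s[0] / s[-1]) == pytest.approx(2.0)

    def test_duplicated_column_is_infinite_not_exception(self):
        mat = np.ones((3, 2))
        assert condition_number(mat) == np.inf

    def test_wide_matrix_is_infinite(self):
        assert condition_number(np.ones((1, 3))) == np.inf


class TestBuildSignature:
    def test_forced_g_on_two_clean_types(self):
        rng = np.random.default_rng(0)
        cols, labels = {}, {}
        for ct, marker in [("A", 0), ("B", 1)]:
            for r in range(3):
                v = rng.normal(5.0, 0.05, 10)
                v[marker] += 5.0
                cols[f"{ct}{r}"] = v
                labels[f"{ct}{r}"] = ct
        ref = ReferenceDataset(
            ExpressionMatrix(pd.DataFrame(cols, index=[f"p{i}" for i in range(10)]), "log2"),
            labels,
        )
        sig = build_signature(ref, g_min=1, g_max=1)
        assert sig.G == 1
        assert sig.data.shape == (2, 2)
        # near-diagonal: own-type marker dominates
        arr = sig.data.to_numpy()
        assert arr[0, 0] > 10 * arr[0, 1]
        assert arr[1, 1] > 10 * arr[1, 0]

    def test_identical_cell_types_hit_degenerate_path(self):
        rng = np.random.default_rng(1)
        base = rng.normal(6, 1, 20)
        cols, labels = {}, {}
        for ct in ["A", "B"]:  # same mean profile -> duplicated columns
            for r in range(3):
                v = base.copy()
                v[0] += 4.0  # shared marker, elevated in both types
                cols[f"{ct}{r}"] = v + rng.normal(0, 1e-6, 20)
                labels[f"{ct}{r}"] = ct
        ref = ReferenceDataset(
            ExpressionMatrix(pd.DataFrame(cols, index=[f"p{i}" for i in range(20)]), "log2"),
            labels,
        )
        try:
            sig = build_signature(ref, g_min=1, g_max=3)
        except ValueError:
            return  # no candidates survive the one-vs-rest filter: also valid
        assert sig.condition_number > 1e6 or sig.provenance.get("degenerate")

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        ref, _ = make_reference(n_types=4, n_probes=80, markers_per_type=6, seed=seed)
        sig = build_signature(ref, g_min=1, g_max=8)
        g_o, probes_o, kappa_o = brute_force_signature_search(
            ref.expression.data, ref.cell_type_of, 1, 8
        )
        assert sig.G == g_o
        assert sorted(sig.probe_ids) == probes_o
        assert sig.condition_number == pytest.approx(kappa_o, rel=1e-9)

    def test_all_planted_markers_selected_at_vanishing_noise(self):
        ref, truth = make_reference(noise_sd=1e-3, seed=5)
        sig = build_signature(ref, g_min=5, g_max=5)
        selected = set(sig.probe_ids)
        for ct, markers in truth.marker_probes.items():
            assert set(markers) <= selected

    def test_permutation_invariance_of_signature_values(self):
        ref, _ = make_reference(seed=7)
        sig = build_signature(ref, g_min=2, g_max=6)
        rng = np.random.default_rng(0)
        perm_samples = list(rng.permutation(ref.expression.sample_ids))
        perm_probes = list(rng.permutation(ref.expression.probe_ids))
        shuffled = ReferenceDataset(
            ExpressionMatrix(ref.expression.data.loc[perm_probes, perm_samples], "log2"),
            ref.cell_type_of,
        )
        sig2 = build_signature(shuffled, g_min=2, g_max=6)
        assert sig2.G == sig.G
        assert set(sig2.probe_ids) == set(sig.probe_ids)
        aligned = sig2.data.loc[sig.data.index, sig.data.columns]
        np.testing.assert_allclose(aligned.to_numpy(), sig.data.to_numpy(), rtol=1e-12)

    def test_empty_candidates_for_a_type_is_error(self):
        # one type identical to the rest of the pool -> nothing differential
        rng = np.random.default_rng(2)
        cols, labels = {}, {}
        for ct, shift in [("A", 4.0), ("B", 0.0), ("C", 0.0)]:
            for r in range(3):
                v = rng.normal(6, 0.1, 15)
                v[0] += shift
                cols[f"{ct}{r}"] = v
                labels[f"{ct}{r}"] = ct
        ref = ReferenceDataset(
            ExpressionMatrix(pd.DataFrame(cols, index=[f"p{i}" for i in range(15)]), "log2"),
            labels,
        )
        with pytest.raises(ValueError, match="no candidate probes"):
            build_signature(ref, g_min=1, g_max=3, q_threshold=1e-6)
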