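import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dermdeconv.stats import (
    adjust_bh,
    paired_compare,
    rank_sum_test,
    signed_rank_test,
    treatment_course,
    unpaired_compare,
)

from oracles import rank_sum_exact_p, signed_rank_exact_p


def make_cohort(values_by_arm, pair=True):
    """Fraction table + metadata for a one-cell-type toy cohort."""
    rows, meta = [], []
    for arm, values in values_by_arm.items():
        for i, v in enumerate(values):
            sid = f"{arm}_{i}"
            rows.append({"ct": v})
            meta.append({"sample_id": sid, "lesional": arm,
                         "subject_id": f"subj{i}" if pair else sid,
                         "timepoint": np.nan})
    idx = [m["sample_id"] for m in meta]
    return (pd.DataFrame(rows, index=idx),
            pd.DataFrame(meta).set_index("sample_id", drop=False))


class TestSignedRank:
    def test_all_zero_differences_give_p_one(self):
        stat, p, dropped = signed_rank_test(np.zeros(6))
        assert p == 1.0 and dropped == 6

    def test_doubling_pairs_example_matches_enumeration(self):
        # before (1,2,3,4,5) vs after (2,4,6,8,10): diffs all one sign
        diffs = np.array([2, 4, 6, 8, 10]) - np.array([1, 2, 3, 4, 5])
        _, p, _ = signed_rank_test(diffs)
        assert p == pytest.approx(0.0625)
        assert p == pytest.approx(signed_rank_exact_p(diffs))

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_sign_assignment_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 9)
        diffs = rng.normal(0.3, 1.0, n)
        _, p, _ = signed_rank_test(diffs)
        assert p == pytest.approx(signed_rank_exact_p(diffs), abs=1e-12)

    def test_negating_differences_leaves_p_unchanged(self):
        rng = np.random.default_rng(1)
        diffs = rng.normal(0.5, 1, 12)
        assert signed_rank_test(diffs)[1] == pytest.approx(signed_rank_test(-diffs)[1])

    def test_exact_close_to_normal_approximation_for_n20(self):
        rng = np.random.default_rng(2)
        diffs = rng.normal(0.4, 1, 20)
        _, p_exact, _ = signed_rank_test(diffs)
        from scipy.stats import wilcoxon

        p_approx = wilcoxon(diffs, correction=True, method="approx").pvalue
        assert abs(p_exact - p_approx) < 0.02


class TestRankSum:
    def test_separated_groups_example_matches_enumeration(self):
        a, b = [1, 2, 3], [4, 5, 6]
        _, p = rank_sum_test(a, b)
        assert p == pytest.approx(0.1)
        assert p == pytest.approx(rank_sum_exact_p(a, b))

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_subset_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, int(rng.integers(3, 7)))
        b = rng.normal(0.5, 1, int(rng.integers(3, 7)))
        _, p = rank_sum_test(a, b)
        assert p == pytest.approx(rank_sum_exact_p(a, b), abs=1e-12)

    def test_identical_groups_give_p_one(self):
        _, p = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 9)
        assert rank_sum_test(a, b)[1] == pytest.approx(rank_sum_test(b, a)[1])

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestAdjustBH:
    def test_single_p_is_identity(self):
        np.testing.assert_allclose(adjust_bh([0.03]), [0.03])

    def test_hand_worked_stepup_example(self):
        # p=(0.01,0.02,0.03,0.04), m=4: q_i = min_{j>=i} p_j*4/j = 0.04 for all
        np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(adjust_bh([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_never_decreases_p_and_preserves_ranks(self, ps):
        q = adjust_bh(ps)
        assert (q >= np.asarray(ps) - 1e-12).all()
        assert (q <= 1 + 1e-12).all()
        # the step-up correction is monotone in the input ranks
        order = np.argsort(ps, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestPairedCompare:
    def test_planted_shift_detected(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0.3, 0.05, 15)
        f, md = make_cohort({"lesional": base + 0.1 + rng.normal(0, 0.01, 15),
                             "non_lesional": base})
        res = paired_compare(f, md, "lesional", "lesional", "non_lesional")
        assert res["p_value"].iloc[0] < 0.01
        assert res["direction"].iloc[0] == 1
        assert res["q_value"].iloc[0] >= res["p_value"].iloc[0] - 1e-12

    def test_no_complete_pairs_is_error(self):
        f, md = make_cohort({"lesional": [0.1, 0.2], "non_lesional": [0.1, 0.2]}, pair=False)
        with pytest.raises(ValueError, match="no complete pairs"):
            paired_compare(f, md, "lesional", "lesional", "non_lesional")

    def test_zero_differences_are_dropped_and_counted(self):
        f, md = make_cohort({"a": [0.1, 0.2, 0.3, 0.5], "b": [0.1, 0.2, 0.3, 0.4]})
        res = paired_compare(f, md, "lesional", "a", "b")
        assert res["n_dropped_zeros"].iloc[0] == 3


class TestUnpairedCompare:
    def test_planted_group_difference_detected(self):
        rng = np.random.default_rng(1)
        f, md = make_cohort({"mild": rng.normal(0.3, 0.03, 14),
                             "severe": rng.normal(0.45, 0.03, 13)}, pair=False)
        res = unpaired_compare(f, md, "lesional", "severe", "mild")
        assert res["p_value"].iloc[0] < 0.001
        assert res["direction"].iloc[0] == 1

    def test_empty_group_is_error(self):
        f, md = make_cohort({"mild": [0.1]}, pair=False)
        with pytest.raises(ValueError):
            unpaired_compare(f, md, "lesional", "mild", "nosuch")


class TestTreatmentCourse:
    @staticmethod
    def course(values_by_timepoint):
        rows, meta = [], []
        for t, values in values_by_timepoint.items():
            for i, v in enumerate(values):
                sid = f"t{t}_s{i}"
                rows.append({"kc": v})
                meta.append({"sample_id": sid, "subject_id": f"subj{i}", "timepoint": t})
        idx = [m["sample_id"] for m in meta]
        return (pd.DataFrame(rows, index=idx),
                pd.DataFrame(meta).set_index("sample_id", drop=False))

    def test_no_change_course_gives_unit_fold_change_and_p_one(self):
        f, md = self.course({0: [0.5, 0.4, 0.3], 1: [0.5, 0.4, 0.3]})
        res = treatment_course(f, md)
        assert res["fold_change"].iloc[0] == pytest.approx(1.0)
        assert res["p_value"].iloc[0] == 1.0

    def test_monotone_decline_recovered(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0.6, 0.02, 8)
        f, md = self.course({0: base, 1: base * 0.8, 2: base * 0.6})
        res = treatment_course(f, md)
        assert (res["fold_change"] < 1).all()
        means = [base.mean(), (base * 0.8).mean(), (base * 0.6).mean()]
        assert means == sorted(means, reverse=True)

    def test_disjoint_subjects_across_timepoints_is_error(self):
        f, md = self.course({0: [0.5, 0.4], 1: [0.5, 0.4]})
        md.loc[md["timepoint"] == 1, "subject_id"] = ["other1", "other2"]
        with pytest.raises(ValueError):
            treatment_course(f, md)


def test_paired_design_more_powerful_than_unpaired_on_shared_subject_effect():
    """With strong subject effects, pairing must sharpen the same contrast."""
    rng = np.random.default_rng(5)
    n = 12
    subj = rng.normal(0, 0.15, n)
    a = 0.40 + subj + rng.normal(0, 0.02, n) + 0.05
    b = 0.40 + subj + rng.normal(0, 0.02, n)
    f, md = make_cohort({"lesional": a, "non_lesional": b})
    p_paired = paired_compare(f, md, "lesional", "lesional", "non_lesional")["p_value"].iloc[0]
    p_unpaired = unpaired_compare(f, md, "lesional", "lesional", "non_lesional")["p_value"].iloc[0]
    assert p_paired < p_unpaired
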