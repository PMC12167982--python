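"""Runs-based permutation test of exchangeability and the variance diagnostic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twinmodels import (
    BinaryTrajectory,
    Panel,
    RealTrajectory,
    TwinParams,
    conditional_variance_profile,
    count_runs,
    dichotomize,
    make_rng,
    mixture_simulate,
    permutation_runs_test,
    polya_simulate,
    pooled_runs,
    twin_simulate,
)


class TestDichotomize:
    def test_median_split_with_ties_dropped(self):
        out = dichotomize(RealTrajectory([1.0, 5.0, 3.0]))
        assert out.values.tolist() == [0, 1]  # the median value 3 is dropped

    def test_tie_policies(self):
        traj = RealTrajectory([1.0, 5.0, 3.0])
        assert dichotomize(traj, tie_policy="assign-low").values.tolist() == [0, 1, 0]
        assert dichotomize(traj, tie_policy="assign-high").values.tolist() == [0, 1, 1]

    def test_all_equal_trajectory_becomes_empty(self):
        assert len(dichotomize(RealTrajectory([2.0, 2.0, 2.0]))) == 0

    def test_even_length_clean_split(self):
        out = dichotomize(RealTrajectory([10.0, 20.0, 30.0, 40.0]))
        assert out.values.tolist() == [0, 0, 1, 1]

    def test_as_is_passthrough_and_validation(self):
        b = BinaryTrajectory([0, 1, 1])
        assert dichotomize(b, rule="as-is") is b
        with pytest.raises(ValueError):
            dichotomize(RealTrajectory([0.0, 2.0]), rule="as-is")

    def test_unknown_options_rejected(self):
        with pytest.raises(ValueError):
            dichotomize(RealTrajectory([1.0]), rule="mean")
        with pytest.raises(ValueError):
            dichotomize(RealTrajectory([1.0]), tie_policy="coin-flip")


class TestCountRuns:
    @pytest.mark.parametrize(
        "seq, expected",
        [([0, 0, 1, 1, 1], 2), ([0, 1, 0, 1], 4), ([], 0), ([1], 1), ([0, 0, 0], 1)],
    )
    def test_examples(self, seq, expected):
        assert count_runs(BinaryTrajectory(seq)) == expected

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.integers(0, 1), max_size=50))
    def test_reversal_and_relabel_invariance(self, bits):
        seq = BinaryTrajectory(bits)
        assert count_runs(seq) == count_runs(BinaryTrajectory(bits[::-1]))
        assert count_runs(seq) == count_runs(BinaryTrajectory([1 - b for b in bits]))


class TestPooledRuns:
    def test_two_unit_example(self):
        panel = Panel({"a": BinaryTrajectory([0, 0, 1]), "b": BinaryTrajectory([1, 0, 1])})
        assert pooled_runs(panel) == 5

    def test_short_units_excluded(self):
        panel = Panel({"a": BinaryTrajectory([0, 0, 1]), "b": BinaryTrajectory([1, 0])})
        assert pooled_runs(panel, min_len=3) == 2

    def test_order_invariance(self):
        a = Panel({"a": BinaryTrajectory([0, 0, 1]), "b": BinaryTrajectory([1, 0, 1])})
        b = Panel({"b": BinaryTrajectory([1, 0, 1]), "a": BinaryTrajectory([0, 0, 1])})
        assert pooled_runs(a) == pooled_runs(b)

    def test_empty_after_filter_rejected(self):
        panel = Panel({"a": BinaryTrajectory([1, 0])})
        with pytest.raises(ValueError):
            pooled_runs(panel, min_len=3)


class TestPermutationTest:
    def test_result_invariants(self):
        panel = mixture_simulate(20, 20, make_rng(1))
        res = permutation_runs_test(panel, n_perm=500, rng=make_rng(2), rule="as-is")
        assert 0 < res.p_two_sided <= 1
        assert 0 <= res.x <= 1
        assert res.n_records_used == 20
        expected = 2 * min(res.x, 1 - res.x)
        if not res.p_is_bound:
            assert res.p_two_sided == pytest.approx(expected)

    def test_constant_panel_reports_bound(self):
        panel = Panel({f"u{i}": BinaryTrajectory([0, 0, 0, 0]) for i in range(5)})
        res = permutation_runs_test(panel, n_perm=200, rng=make_rng(3), rule="as-is")
        assert res.p_is_bound
        assert res.p_two_sided == pytest.approx(2 / 200)
        assert res.x == 0.0

    def test_seeded_reproducibility(self):
        panel = mixture_simulate(20, 15, make_rng(4))
        r1 = permutation_runs_test(panel, n_perm=300, rng=make_rng(5), rule="as-is")
        r2 = permutation_runs_test(panel, n_perm=300, rng=make_rng(5), rule="as-is")
        assert r1.x == r2.x and r1.p_two_sided == r2.p_two_sided

    def test_alternating_panel_rejected_as_too_many_runs(self):
        """Perfectly alternating records have far more runs than shuffles."""
        panel = Panel({f"u{i}": BinaryTrajectory([0, 1] * 10) for i in range(20)})
        res = permutation_runs_test(panel, n_perm=1000, rng=make_rng(6), rule="as-is")
        assert res.x == 1.0 or res.x > 0.99
        assert res.p_two_sided < 0.05

    def test_smoothed_estimator(self):
        panel = mixture_simulate(20, 15, make_rng(7))
        res = permutation_runs_test(
            panel, n_perm=100, rng=make_rng(8), rule="as-is", smoothed=True
        )
        assert 0 < res.x < 1  # add-one smoothing keeps x off the boundary

    def test_type_one_error_near_nominal_under_exchangeable_null(self):
        """Rejection rate ~5% over exchangeable mixture panels (small replicate)."""
        root = make_rng(9)
        rej = 0
        n_rep = 100
        for i in range(n_rep):
            panel = mixture_simulate(20, 30, root.substream("panel", i))
            res = permutation_runs_test(
                panel, n_perm=400, rng=root.substream("perm", i), rule="as-is"
            )
            rej += res.p_two_sided <= 0.05
        assert 0.0 <= rej / n_rep <= 0.12

    def test_polya_panels_also_calibrated(self):
        """Pólya draws are exchangeable, so the shuffle null holds for them
        too: the runs test must NOT systematically reject the urn."""
        root = make_rng(10)
        rej = 0
        n_rep = 60
        for i in range(n_rep):
            panel = polya_simulate(30, 30, root.substream("panel", i))
            res = permutation_runs_test(
                panel, n_perm=400, rng=root.substream("perm", i), rule="as-is"
            )
            rej += res.p_two_sided <= 0.05
        assert rej / n_rep <= 0.15

    def test_keep_permutations(self):
        panel = mixture_simulate(10, 10, make_rng(11))
        res = permutation_runs_test(
            panel, n_perm=50, rng=make_rng(12), rule="as-is", keep_permutations=True
        )
        assert res.permuted_sums.shape == (50,)


class TestConditionalVarianceProfile:
    T = TwinParams(0.0, 1.0, 5.0)

    def test_self_consistency_on_twin_output(self):
        panel = twin_simulate(self.T, 4000, 8, make_rng(13))
        profile = conditional_variance_profile(panel, self.T)
        for _, row in profile.iterrows():
            # sampling SE of a variance estimate: var*sqrt(2/(n-1))
            se = row.predicted_variance * np.sqrt(2 / (row.n_units - 1))
            assert abs(row.residual_variance - row.predicted_variance) < 4 * se

    def test_first_entry_definition(self):
        panel = twin_simulate(self.T, 500, 2, make_rng(14))
        mat = panel.values_matrix()
        resid = mat[:, 1] - (self.T.c * self.T.a + mat[:, 0]) / (1 + self.T.c)
        profile = conditional_variance_profile(panel, self.T)
        row = profile[profile.n == 1].iloc[0]
        assert row.residual_variance == pytest.approx(np.var(resid, ddof=1), rel=1e-10)

    def test_flat_variance_panel_flagged(self):
        """i.i.d. innovations with constant variance violate the shrinking
        schedule: late residual variances sit well below the n=0 prediction
        ratio implied by the twin."""
        gen = make_rng(15).generator()
        panel = Panel(
            {f"u{i}": RealTrajectory(gen.normal(0, 1, size=8)) for i in range(4000)}
        )
        t = TwinParams(0.0, 1.0, 1.0)  # predicts variance 2 at n=0, ~1 late
        profile = conditional_variance_profile(panel, t)
        early = profile.iloc[0]
        assert early.residual_variance < early.predicted_variance * 0.75

    def test_sparse_lengths_skipped_with_warning(self):
        panel = Panel(
            {"a": RealTrajectory([1.0, 2.0, 3.0]), "b": RealTrajectory([1.0])}
        )
        with pytest.warns(UserWarning):
            profile = conditional_variance_profile(panel, self.T)
        assert set(profile.n) == {0}
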