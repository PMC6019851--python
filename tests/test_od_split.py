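import numpy as np
import pytest

import fnirsdpf as f
from fnirsdpf import TimeSeries
from fnirsdpf.od_split import CASES, J1_COEF_L1, J1_COEF_L2, TRUE_DPF_L1, TRUE_DPF_L2


def grid_split_oracle(v, case, n=201, rounds=5, mu=1e-10):
    """Brute-force split of one sample: refine a quadrant grid minimising
    the penalised objective residual^2 + mu * norm^2 (mu breaks the tie
    between exact solutions in favour of the minimum-norm one)."""
    c1, c2 = J1_COEF_L1, J1_COEF_L2
    span = abs(v) + 1.0
    centre = np.array([0.0, 0.0])
    width = np.array([1.2 * span / c1, 1.2 * span / c2])
    best = centre
    for _ in range(rounds):
        lo = centre - width
        hi = centre + width
        # clip the box to the case's quadrant
        if case.sign_l1 > 0:
            lo[0] = max(lo[0], 0.0)
        else:
            hi[0] = min(hi[0], 0.0)
        if case.sign_l2 > 0:
            lo[1] = max(lo[1], 0.0)
        else:
            hi[1] = min(hi[1], 0.0)
        g1 = np.linspace(lo[0], hi[0], n)
        g2 = np.linspace(lo[1], hi[1], n)
        O1, O2 = np.meshgrid(g1, g2, indexing="ij")
        res2 = (v - c2 * O2 + c1 * O1) ** 2
        objective = res2 + mu * (O1**2 + O2**2)
        i, j = np.unravel_index(np.argmin(objective), objective.shape)
        centre = np.array([g1[i], g2[j]])
        best = centre
        width = 3.0 * (hi - lo) / (n - 1)
    return best


class TestJ1Residual:
    def test_zero_everything_is_zero(self):
        y = TimeSeries(np.zeros(5), 1.0)
        pair = f.ODPair(y.copy_with(np.zeros(5)), y.copy_with(np.zeros(5)), 1.0, 1.0)
        assert f.j1_residual(y, pair) == 0.0

    def test_printed_constants(self):
        y = TimeSeries([0.0], 1.0)
        pair_l2 = f.ODPair(y.copy_with([0.0]), y.copy_with([1.0]), 1.0, 1.0)
        assert np.sqrt(f.j1_residual(y, pair_l2)) == pytest.approx(0.0375, abs=1e-12)
        pair_l1 = f.ODPair(y.copy_with([1.0]), y.copy_with([0.0]), 1.0, 1.0)
        assert np.sqrt(f.j1_residual(y, pair_l1)) == pytest.approx(0.01644, abs=1e-12)

    def test_exact_split_has_zero_residual(self, noise_free_subject):
        y, pair, _, _ = noise_free_subject
        assert f.j1_residual(y, pair) < 1e-18 * len(y)


class TestSplitSignal:
    def test_zero_sample_maps_to_origin(self):
        y = TimeSeries([0.0, 0.0], 1.0)
        for case in CASES.values():
            result = f.split_signal(y, case)
            assert np.all(result.pair.od_l1.values == 0)
            assert np.all(result.pair.od_l2.values == 0)
            assert result.infeasible_fraction == 0.0

    def test_case4_minimum_norm_closed_form(self):
        # projection of the origin onto the solution line for y = 1
        result = f.split_signal(TimeSeries([1.0], 1.0), "case4")
        # y * (-c1, c2) / (c1^2 + c2^2) evaluated independently
        assert result.pair.od_l1.values[0] == pytest.approx(-9.8062, abs=2e-3)
        assert result.pair.od_l2.values[0] == pytest.approx(22.3677, abs=2e-3)
        assert result.residual_j1 == 0.0

    def test_case4_negative_sample_infeasible(self):
        result = f.split_signal(TimeSeries([-1.0], 1.0), "case4")
        assert result.infeasible_fraction == 1.0
        assert result.pair.od_l1.values[0] == 0.0
        assert result.pair.od_l2.values[0] == 0.0
        assert result.residual_j1 == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        v = rng.normal(scale=2.0, size=50)
        y = TimeSeries(v, 1.0)
        for case in CASES.values():
            result = f.split_signal(y, case)
            od1, od2 = result.pair.od_l1.values, result.pair.od_l2.values
            for k, vk in enumerate(v):
                o1, o2 = grid_split_oracle(vk, case)
                norm_diff = np.hypot(od1[k] - o1, od2[k] - o2)
                assert norm_diff < 1e-3, (case.label, k, vk)
                res_mine = (vk - J1_COEF_L2 * od2[k] + J1_COEF_L1 * od1[k]) ** 2
                res_oracle = (vk - J1_COEF_L2 * o2 + J1_COEF_L1 * o1) ** 2
                assert abs(res_mine - res_oracle) < 1e-6

    def test_residual_zero_iff_all_feasible(self):
        rng = np.random.default_rng(23)
        y = TimeSeries(rng.normal(size=200), 10.0)
        for case in CASES.values():
            result = f.split_signal(y, case)
            if result.infeasible_fraction == 0.0:
                assert result.residual_j1 == 0.0
            else:
                assert result.residual_j1 > 0.0
            # infeasibility only ever strikes the sign-impossible cases
            if case.label in ("case1", "case2"):
                assert result.infeasible_fraction == 0.0

    def test_sign_constraints_respected(self):
        rng = np.random.default_rng(29)
        y = TimeSeries(rng.normal(size=100), 10.0)
        for case in CASES.values():
            result = f.split_signal(y, case)
            assert np.all(case.sign_l1 * result.pair.od_l1.values >= 0)
            assert np.all(case.sign_l2 * result.pair.od_l2.values >= 0)

    def test_case3_case4_partition_signs(self):
        rng = np.random.default_rng(31)
        v = rng.normal(size=300)
        y = TimeSeries(v, 10.0)
        rec3 = f.reconstruct_under_dpf(f.split_signal(y, "case3"), TRUE_DPF_L1, TRUE_DPF_L2)
        rec4 = f.reconstruct_under_dpf(f.split_signal(y, "case4"), TRUE_DPF_L1, TRUE_DPF_L2)
        np.testing.assert_allclose(rec3.values, np.minimum(v, 0.0), atol=1e-12)
        np.testing.assert_allclose(rec4.values, np.maximum(v, 0.0), atol=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            f.split_signal(TimeSeries([1.0, np.nan], 1.0), "case1")

    def test_unknown_case_rejected(self):
        with pytest.raises(ValueError, match="case9"):
            f.split_signal(TimeSeries([1.0], 1.0), "case9")


class TestReconstructUnderDPF:
    def test_true_dpfs_invert_the_split(self, noise_free_subject):
        y, _, _, _ = noise_free_subject
        for case in ("case1", "case2"):
            result = f.split_signal(y, case)
            rec = f.reconstruct_under_dpf(result, TRUE_DPF_L1, TRUE_DPF_L2)
            np.testing.assert_allclose(rec.values, y.values, atol=1e-12)

    def test_case1_reconstruction_nondecreasing_in_dpf_l1(self, noise_free_subject):
        y, _, _, _ = noise_free_subject
        result = f.split_signal(y, "case1")
        rec3 = f.reconstruct_under_dpf(result, 3.0, TRUE_DPF_L2)
        rec8 = f.reconstruct_under_dpf(result, 8.0, TRUE_DPF_L2)
        assert np.all(rec8.values >= rec3.values - 1e-12)

    def test_case2_translates_downward_as_dpf_l1_rises(self, noise_free_subject):
        # case 2 puts the positive part of the signal on a negative od_l1;
        # raising dpf_l1 shrinks its (positive) contribution
        y, _, _, _ = noise_free_subject
        result = f.split_signal(y, "case2")
        assert np.any(result.pair.od_l1.values < 0)
        rec3 = f.reconstruct_under_dpf(result, 3.0, TRUE_DPF_L2)
        rec8 = f.reconstruct_under_dpf(result, 8.0, TRUE_DPF_L2)
        negative_od1 = result.pair.od_l1.values < 0
        assert np.all(rec8.values[negative_od1] < rec3.values[negative_od1])

    def test_nonpositive_dpf_rejected(self, noise_free_subject):
        y, _, _, _ = noise_free_subject
        result = f.split_signal(y, "case1")
        with pytest.raises(ValueError, match="DPF"):
            f.reconstruct_under_dpf(result, -3.0, 5.0)
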