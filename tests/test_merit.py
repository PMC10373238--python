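import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import chemocal as cc

from reference_tables import (
    STD_ADDITION_CLS_COMP1,
    STD_ADDITION_CLS_COMP2,
    VALIDATION_RECOVERY,
)


class TestRecoverySummary:
    def test_reproduces_published_validation_mean(self):
        rec = VALIDATION_RECOVERY[("cls", "comp1")]
        s = cc.recovery_summary(rec, [100.0] * len(rec))
        assert round(s.mean, 2) == 101.30

    def test_reproduces_published_validation_rsd(self):
        rec = VALIDATION_RECOVERY[("pcr", "comp1")]
        s = cc.recovery_summary(rec, [100.0] * len(rec))
        assert round(s.rsd, 3) == 0.126

    def test_constant_recoveries(self):
        s = cc.recovery_summary([100.0, 100.0, 100.0], [100.0] * 3)
        assert (s.mean, s.sd, s.rsd) == (100.0, 0.0, 0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            cc.recovery_summary([1.0, 2.0], [1.0])

    @given(st.lists(st.floats(50, 150), min_size=2, max_size=20),
           st.floats(0.5, 20))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_numpy_oracle(self, recoveries, nominal):
        pred = [r * nominal / 100 for r in recoveries]
        s = cc.recovery_summary(pred, [nominal] * len(pred))
        assert s.mean == pytest.approx(np.mean(recoveries), rel=1e-9)
        assert s.sd == pytest.approx(np.std(recoveries, ddof=1), rel=1e-9, abs=1e-9)


class TestLodLoq:
    def test_direct_substitution(self):
        lod, loq = cc.lod_loq(cc.MeritInputs(slope=1.0, sd_residual=0.1))
        assert (lod, loq) == (pytest.approx(0.33), pytest.approx(1.0))

    def test_ratio_is_constant(self):
        lod, loq = cc.lod_loq(cc.MeritInputs(slope=0.7, sd_residual=0.03))
        assert loq / lod == pytest.approx(10 / 3.3)

    def test_zero_residual_sd(self):
        assert cc.lod_loq(cc.MeritInputs(slope=2.0, sd_residual=0.0)) == (0.0, 0.0)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            cc.MeritInputs(slope=0.0, sd_residual=0.1)

    def test_linearity_merit_residual_sd_divisor(self):
        x = np.array([1, 5, 9, 13, 17.0])
        y = 1.02 * x + np.array([0.1, -0.1, 0.0, 0.1, -0.1])
        mi = cc.linearity_merit(x, y)
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        assert mi.slope == pytest.approx(slope)
        assert mi.sd_residual == pytest.approx(np.sqrt((resid**2).sum() / 3))


@pytest.fixture(scope="module")
def fitted(calibration_blocks, grid):
    C, A = calibration_blocks
    return cc.fit_pls(C, A, 2, wavelengths=grid.wavelengths)


class TestProtocols:

    def test_noiseless_accuracy_is_100(self, fitted, grid):
        acc = cc.accuracy_protocol(fitted, cc.DEFAULT_COMPONENTS,
                                   cc.NoiseModel(seed=0, noise_sd=0.0), grid)
        for s in acc.pooled:
            assert s.mean == pytest.approx(100.0, abs=1e-6)
            assert s.n == 9

    def test_accuracy_is_seed_reproducible(self, fitted, grid):
        noise = cc.NoiseModel(seed=11, noise_sd=0.002)
        a = cc.accuracy_protocol(fitted, cc.DEFAULT_COMPONENTS, noise, grid)
        b = cc.accuracy_protocol(fitted, cc.DEFAULT_COMPONENTS, noise, grid)
        assert np.array_equal(a.pooled[0].recoveries, b.pooled[0].recoveries)

    def test_level_outside_range_warns(self, fitted, grid):
        with pytest.warns(UserWarning, match="outside calibrated range"):
            cc.accuracy_protocol(fitted, cc.DEFAULT_COMPONENTS,
                                 cc.NoiseModel(seed=0, noise_sd=0.0), grid,
                                 levels=(4.0, 25.0))

    def test_noiseless_precision_is_zero(self, fitted, grid):
        prec = cc.precision_protocol(fitted, cc.DEFAULT_COMPONENTS,
                                     cc.NoiseModel(seed=0, noise_sd=0.0), grid)
        assert np.allclose(prec.repeatability_rsd, 0.0, atol=1e-6)
        assert np.allclose(prec.intermediate_rsd, 0.0, atol=1e-6)

    def test_three_days_pool_27_recoveries(self, fitted, grid):
        prec = cc.precision_protocol(fitted, cc.DEFAULT_COMPONENTS,
                                     cc.NoiseModel(seed=2, noise_sd=0.002), grid,
                                     day_seeds=(21, 22, 23))
        assert prec.recoveries_by_day.shape == (3, 9, 2)

    def test_between_day_drift_inflates_intermediate_rsd(self, fitted, grid):
        noise = cc.NoiseModel(seed=2, noise_sd=0.002)
        drift = cc.precision_protocol(fitted, cc.DEFAULT_COMPONENTS, noise, grid,
                                      day_seeds=(31, 32, 33), between_day_sd=0.01)
        assert np.all(drift.intermediate_rsd >= drift.repeatability_rsd)


class TestStandardAddition:
    def test_single_row_recovery(self):
        row = cc.StdAdditionRow(2.0, 1.99, 3.0, 3.02)
        assert round(row.recovery, 2) == 100.67

    def test_published_rows_give_published_mean(self):
        res = cc.standard_addition(
            [cc.StdAdditionRow(*r) for r in STD_ADDITION_CLS_COMP1])
        assert round(res.mean, 2) == 100.52
        res2 = cc.standard_addition(
            [cc.StdAdditionRow(*r) for r in STD_ADDITION_CLS_COMP2])
        assert round(res2.mean, 2) == 100.18

    def test_found_equals_added_gives_100(self):
        res = cc.standard_addition([cc.StdAdditionRow(1.0, 1.0, 5.0, 5.0)])
        assert res.recoveries[0] == pytest.approx(100.0)

    def test_nonpositive_addition_rejected(self):
        with pytest.raises(ValueError):
            cc.StdAdditionRow(1.0, 1.0, 0.0, 1.0)


class TestCompareMethods:
    def test_critical_values_at_p05(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(100, 1, 5), rng.normal(100, 1, 5)
        out = cc.compare_methods(x, y)
        assert round(out.t_crit, 3) == 2.306
        assert round(out.f_crit, 3) == 6.388
        assert out.t_df == 8 and out.f_df in ((4, 4),)

    def test_identical_samples_not_significant(self):
        x = [99.1, 100.2, 100.9, 99.6, 100.3]
        out = cc.compare_methods(x, x)
        assert out.t_stat == pytest.approx(0.0)
        assert out.f_stat == pytest.approx(1.0)
        assert out.verdict == "not significant"

    def test_symmetry_up_to_t_sign(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(100, 1, 5), rng.normal(101, 2, 6)
        a, b = cc.compare_methods(x, y), cc.compare_methods(y, x)
        assert a.t_stat == pytest.approx(-b.t_stat)
        assert a.f_stat == pytest.approx(b.f_stat)
        assert a.f_df == b.f_df

    def test_zero_variance_both_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            cc.compare_methods([1.0, 1.0], [2.0, 2.0])

    def test_detects_a_clear_difference(self):
        out = cc.compare_methods([100, 100.1, 99.9, 100, 100.1],
                                 [103, 103.1, 102.9, 103, 103.2])
        assert out.t_significant and out.verdict == "significant"
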