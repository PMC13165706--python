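"""Pre-processing operators: exactness, idempotence, fit/apply contract."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from honeynir.preprocess import (
    PreprocessSpec,
    detrend_linear,
    enumerate_grid,
    fit_apply,
    msc,
    savitzky_golay,
    snv,
)


class TestSNV:
    def test_hand_example(self):
        np.testing.assert_allclose(snv(np.array([[1.0, 2.0, 3.0]])),
                                   [[-1.0, 0.0, 1.0]])

    def test_rows_standardised_and_idempotent(self, rng):
        X = rng.normal(size=(20, 50)) * 3 + 1
        Z = snv(X)
        np.testing.assert_allclose(Z.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=1, ddof=1), 1, atol=1e-12)
        np.testing.assert_allclose(snv(Z), Z, atol=1e-12)

    def test_constant_row_rejected(self):
        with pytest.raises(ValueError, match="row 1"):
            snv(np.array([[1.0, 2.0], [5.0, 5.0]]))


class TestMSC:
    def test_identity_when_rows_equal_reference(self, rng):
        ref = rng.normal(size=30)
        X = np.tile(ref, (4, 1))
        corrected, used = msc(X, ref)
        np.testing.assert_allclose(corrected, X, atol=1e-10)
        np.testing.assert_array_equal(used, ref)

    def test_affine_row_maps_back_to_reference(self, rng):
        ref = rng.normal(size=30)
        row = 2.0 * ref + 5.0
        corrected, _ = msc(row[None, :], ref)
        np.testing.assert_allclose(corrected[0], ref, atol=1e-10)

    def test_calibration_reference_reused_on_validation(self, rng):
        X_cal = rng.normal(size=(10, 25)) + 2.0
        X_val = rng.normal(size=(4, 25)) - 1.0
        against_cal, _ = msc(X_val, X_cal.mean(axis=0))
        self_ref, _ = msc(X_val, None)
        assert not np.allclose(against_cal, self_ref)

    def test_degenerate_slope_rejected(self, rng):
        ref = rng.normal(size=10)
        noise_row = np.zeros((1, 10))  # slope ~ 0 against the reference
        with pytest.raises(ValueError, match="degenerate"):
            msc(noise_row, ref)


class TestDetrend:
    def test_linear_row_goes_to_zero(self):
        row = 3.0 * np.arange(8.0) + 1.0
        np.testing.assert_allclose(detrend_linear(row[None, :]), 0, atol=1e-10)

    def test_quadratic_residual_matches_ols_oracle(self):
        # x_j = j^2 on j=0..4; the closed-form OLS line over the index is
        # 6 + 4*(j-2), residuals [2, -1, -2, -1, 2]
        row = np.array([[0.0, 1.0, 4.0, 9.0, 16.0]])
        res = detrend_linear(row)
        np.testing.assert_allclose(res, [[2.0, -1.0, -2.0, -1.0, 2.0]], atol=1e-10)
        assert abs(res.sum()) < 1e-10

    def test_idempotent(self, rng):
        X = rng.normal(size=(6, 40))
        once = detrend_linear(X)
        np.testing.assert_allclose(detrend_linear(once), once, atol=1e-10)


class TestSavitzkyGolay:
    @pytest.mark.parametrize("window", [5, 9, 15, 21])
    def test_first_derivative_of_line_is_slope(self, window):
        lam = 850.0 + 0.5 * np.arange(200)
        row = 3.0 * lam + 2.0
        d = savitzky_golay(row[None, :], window, 2, deriv=1, grid_step=0.5)
        np.testing.assert_allclose(d, 3.0, atol=1e-8)

    def test_second_derivative_of_square(self):
        lam = np.arange(100.0)
        row = lam**2
        d = savitzky_golay(row[None, :], 7, 2, deriv=2, grid_step=1.0)
        np.testing.assert_allclose(d, 2.0, atol=1e-8)

    def test_derivative_scaled_to_grid_units(self):
        lam = 1000.0 + 2.0 * np.arange(50)
        row = 5.0 * lam
        d = savitzky_golay(row[None, :], 7, 2, deriv=1, grid_step=2.0)
        np.testing.assert_allclose(d, 5.0, atol=1e-8)

    def test_smoothing_constant_and_window_one(self, rng):
        row = np.full((1, 30), 7.0)
        np.testing.assert_allclose(savitzky_golay(row, 9, 2, 0), 7.0)
        X = rng.normal(size=(3, 30))
        np.testing.assert_array_equal(savitzky_golay(X, 1, 2, 0), X)

    def test_parameter_errors(self, rng):
        X = rng.normal(size=(2, 30))
        with pytest.raises(ValueError):
            savitzky_golay(X, 8, 2, 0)  # even window
        with pytest.raises(ValueError):
            savitzky_golay(X, 3, 3, 0)  # window <= polyorder
        with pytest.raises(ValueError):
            savitzky_golay(X, 7, 2, 3)  # deriv > polyorder


class TestSpecAndGrid:
    def test_spec_invariants(self):
        with pytest.raises(ValueError):
            PreprocessSpec(sg_window=1, sg_deriv=1)
        with pytest.raises(ValueError):
            PreprocessSpec(sg_window=3, sg_polyorder=3)
        with pytest.raises(ValueError):
            PreprocessSpec(scatter="osc")

    def test_grid_count_matches_brute_force(self):
        specs = enumerate_grid()
        # independent brute-force count of valid combinations
        count = 0
        for _scatter in range(3):
            for _detrend in range(2):
                sg = 1  # no-filtering variant
                for w in range(3, 22, 2):
                    for po in (2, 3):
                        for dv in (0, 1, 2):
                            if w > po and dv <= po:
                                sg += 1
                for _scaling in range(3):
                    count += sg
        assert len(specs) == count == 1044

    def test_ids_unique_and_constraints_respected(self):
        specs = enumerate_grid()
        labels = [s.label for s in specs]
        assert len(set(labels)) == len(labels)
        only_snv = enumerate_grid(scatters=("snv",))
        assert all(s.scatter == "snv" for s in only_snv)

    def test_label_notation(self):
        spec = PreprocessSpec(scatter="snv", detrend=True, sg_window=7,
                              sg_polyorder=2, sg_deriv=1, scaling="autoscale")
        assert spec.label == ("SNV + linear detrending + SG (7, poly 2) "
                              "1st derivative + mean centring + scaling")
        assert PreprocessSpec().label == "no Savitzky-Golay filtering"


class TestFitApply:
    def test_identity_pipeline(self, rng):
        X = rng.normal(size=(8, 20))
        Xc, Xv, _ = fit_apply(PreprocessSpec(), X, X[:3])
        np.testing.assert_array_equal(Xc, X)
        np.testing.assert_array_equal(Xv, X[:3])

    def test_autoscale_contract(self, rng):
        spec = PreprocessSpec(scaling="autoscale")
        X_cal = rng.normal(size=(12, 15)) * 2 + 3
        X_val = rng.normal(size=(5, 15)) * 5
        Xc, Xv, _ = fit_apply(spec, X_cal, X_val)
        np.testing.assert_allclose(Xc.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(Xc.std(axis=0, ddof=1), 1, atol=1e-12)
        assert np.abs(Xv.mean(axis=0)).max() > 1e-3  # validation not re-centred

    def test_composition_equals_standalone_operators(self, rng):
        spec = PreprocessSpec(scatter="snv", sg_window=7, sg_polyorder=2,
                              sg_deriv=1)
        X = rng.normal(size=(6, 60)).cumsum(axis=1)
        Xc, _, _ = fit_apply(spec, X, grid_step=0.5)
        manual = savitzky_golay(snv(X), 7, 2, 1, grid_step=0.5)
        np.testing.assert_allclose(Xc, manual, atol=1e-12)

    def test_validation_rows_never_leak_into_fit(self, rng):
        spec = PreprocessSpec(scatter="msc", scaling="autoscale")
        X_cal = rng.normal(size=(10, 30)).cumsum(axis=1) + 5
        X_val = rng.normal(size=(4, 30)).cumsum(axis=1) + 5
        Xc1, _, _ = fit_apply(spec, X_cal, X_val)
        Xc2, _, _ = fit_apply(spec, X_cal, X_val * 100 + 7)
        np.testing.assert_array_equal(Xc1, Xc2)

    def test_column_count_mismatch(self, rng):
        with pytest.raises(ValueError, match="column count"):
            fit_apply(PreprocessSpec(), rng.normal(size=(4, 10)),
                      rng.normal(size=(4, 11)))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_snv_property_random_matrices(seed):
    """SNV output rows always have mean 0 and sample SD 1."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(5, 12)) * rng.uniform(0.5, 10) + rng.uniform(-5, 5)
    Z = snv(X)
    np.testing.assert_allclose(Z.mean(axis=1), 0, atol=1e-10)
    np.testing.assert_allclose(Z.std(axis=1, ddof=1), 1, atol=1e-10)
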