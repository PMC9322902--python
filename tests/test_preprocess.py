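"""Transform arithmetic oracles, airPLS baseline recovery, and recipes."""

import numpy as np
import pytest

import ftirclass as fc
from ftirclass.core import SpectraError
from ftirclass.preprocess import AirPLSParams, airpls

from conftest import toy_set

RNG = np.random.default_rng(2024)


class TestSnv:
    def test_small_example(self):
        out = fc.snv(toy_set([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out.values, [[-1.0, 0.0, 1.0]])

    def test_idempotent(self):
        s = toy_set(RNG.normal(size=(3, 40)))
        once = fc.snv(s)
        np.testing.assert_allclose(fc.snv(once).values, once.values,
                                   atol=1e-12)

    def test_matches_two_pass_oracle(self):
        row = RNG.normal(size=60)
        mu = sum(row) / 60
        sd = np.sqrt(sum((x - mu) ** 2 for x in row) / 59)
        out = fc.snv(toy_set([row]))
        np.testing.assert_allclose(out.values[0], (row - mu) / sd, atol=1e-12)

    def test_constant_row_rejected(self):
        with pytest.raises(SpectraError, match="s0"):
            fc.snv(toy_set([[2.0, 2.0, 2.0]]))


class TestMsc:
    def test_reference_is_fixed_point(self):
        ref = RNG.uniform(0.1, 1.0, 50)
        out = fc.msc(toy_set([ref]), reference=ref)
        np.testing.assert_allclose(out.values[0], ref, atol=1e-10)

    def test_exact_linear_model_recovered(self):
        ref = RNG.uniform(0.1, 1.0, 50)
        out = fc.msc(toy_set([2.0 * ref + 3.0]), reference=ref)
        np.testing.assert_allclose(out.values[0], ref, atol=1e-9)

    def test_coefficients_match_closed_form_regression(self):
        ref = RNG.uniform(0.1, 1.0, 80)
        x = RNG.normal(size=80) + 0.5 * ref
        # simple-regression closed form for x ~ a*ref + b
        a = np.cov(x, ref, ddof=1)[0, 1] / np.var(ref, ddof=1)
        b = x.mean() - a * ref.mean()
        out = fc.msc(toy_set([x]), reference=ref)
        np.testing.assert_allclose(out.values[0], (x - b) / a, atol=1e-9)

    def test_default_reference_is_column_mean(self):
        s = toy_set(RNG.uniform(0.1, 1.0, (4, 30)))
        ref = s.values.mean(axis=0)
        np.testing.assert_allclose(fc.msc(s).values,
                                   fc.msc(s, reference=ref).values)


class TestSavitzkyGolay:
    def test_first_derivative_of_constant_is_zero(self):
        out = fc.savitzky_golay(toy_set([np.full(30, 7.0)]), deriv=1)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_first_derivative_of_quadratic_is_linear(self):
        t = np.arange(30.0)
        out = fc.savitzky_golay(toy_set([t ** 2]), window=9, polyorder=2,
                                deriv=1)
        np.testing.assert_allclose(out.values[0][4:-4], 2 * t[4:-4],
                                   atol=1e-9)

    def test_smoothing_is_exact_on_low_degree_polynomials(self):
        t = np.arange(40.0)
        row = 3.0 - 0.5 * t + 0.01 * t ** 2
        out = fc.savitzky_golay(toy_set([row]), window=9, polyorder=2,
                                deriv=0)
        np.testing.assert_allclose(out.values[0], row, atol=1e-9)

    def test_window_validation(self):
        with pytest.raises(SpectraError):
            fc.savitzky_golay(toy_set([np.arange(5.0)]), window=9)
        with pytest.raises(SpectraError):
            fc.savitzky_golay(toy_set([np.arange(30.0)]), window=8)


class TestVectorNormalize:
    def test_three_four_five(self):
        out = fc.vector_normalize(toy_set([[3.0, 4.0]]))
        np.testing.assert_allclose(out.values, [[0.6, 0.8]])

    def test_unit_norm_and_scale_invariance(self):
        s = toy_set(RNG.normal(size=(5, 64)))
        out = fc.vector_normalize(s)
        np.testing.assert_allclose(np.linalg.norm(out.values, axis=1), 1.0,
                                   atol=1e-12)
        scaled = fc.vector_normalize(s.with_values(s.values * 17.3))
        np.testing.assert_allclose(scaled.values, out.values, atol=1e-12)


class TestAreaNormalize:
    def test_constant_over_default_grid(self):
        s = toy_set(np.ones((1, fc.DEFAULT_GRID.size)), grid=fc.DEFAULT_GRID)
        out = fc.area_normalize(s)
        np.testing.assert_allclose(out.values, 1.0 / 3400.0)

    def test_output_areas_are_one(self):
        s = toy_set(RNG.uniform(0.1, 1.0, (4, fc.DEFAULT_GRID.size)),
                    grid=fc.DEFAULT_GRID)
        out = fc.area_normalize(s)
        areas = np.abs(np.trapezoid(out.values, x=out.wavenumbers, axis=1))
        np.testing.assert_allclose(areas, 1.0, atol=1e-9)

    def test_matches_bruteforce_trapezoid(self):
        grid = np.array([10.0, 8.0, 6.0, 4.0])
        row = np.array([1.0, 2.0, 4.0, 8.0])
        # hand trapezoid on the descending grid, |integral|
        area = sum((row[i] + row[i + 1]) / 2 * 2.0 for i in range(3))
        out = fc.area_normalize(toy_set([row], grid=grid))
        np.testing.assert_allclose(out.values[0], row / area, atol=1e-12)


class TestMinMax:
    def test_range_division_default(self):
        out = fc.minmax_normalize(toy_set([[0.0, 1.0, 2.0]]))
        np.testing.assert_allclose(out.values, [[0.0, 0.5, 1.0]])

    def test_default_mode_is_not_shift_invariant(self):
        # dividing by the range leaves the offset in place: shifting the
        # input shifts the output
        out = fc.minmax_normalize(toy_set([[5.0, 6.0, 7.0]]))
        np.testing.assert_allclose(out.values, [[2.5, 3.0, 3.5]])
        unit = fc.minmax_normalize(toy_set([[5.0, 5.5, 6.0]]))
        np.testing.assert_allclose(unit.values, [[5.0, 5.5, 6.0]])

    def test_conventional_variant(self):
        out = fc.minmax_normalize(toy_set([[5.0, 6.0, 7.0]]),
                                  conventional=True)
        np.testing.assert_allclose(out.values, [[0.0, 0.5, 1.0]])


class TestRowCenter:
    def test_example_and_idempotence(self):
        out = fc.row_center(toy_set([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out.values, [[-1.0, 0.0, 1.0]])
        s = toy_set(RNG.normal(size=(3, 20)))
        once = fc.row_center(s)
        np.testing.assert_allclose(once.values.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(fc.row_center(once).values, once.values,
                                   atol=1e-12)


class TestEwma:
    def test_lam_one_is_identity(self):
        s = toy_set(RNG.normal(size=(2, 25)))
        np.testing.assert_allclose(fc.ewma_smooth(s, lam=1.0).values,
                                   s.values, atol=1e-12)

    def test_constant_row_unchanged(self):
        s = toy_set([np.full(12, 3.3)])
        np.testing.assert_allclose(fc.ewma_smooth(s, lam=0.3).values,
                                   s.values, atol=1e-12)

    def test_hand_recursion(self):
        out = fc.ewma_smooth(toy_set([[0.0, 1.0, 1.0]]), lam=0.5)
        np.testing.assert_allclose(out.values, [[0.0, 0.5, 0.75]])

    def test_lam_range_enforced(self):
        with pytest.raises(SpectraError):
            fc.ewma_smooth(toy_set([[1.0, 2.0]]), lam=0.0)


class TestAtrCorrect:
    def test_reference_point_unchanged_and_linearity(self):
        grid = np.array([2000.0, 1000.0, 500.0])
        s = toy_set([[1.0, 1.0, 1.0]], grid=grid)
        out = fc.atr_correct(s, ref_wavenumber=1000.0)
        np.testing.assert_allclose(out.values, [[2.0, 1.0, 0.5]])
        double = fc.atr_correct(s.with_values(2 * s.values), 1000.0)
        np.testing.assert_allclose(double.values, 2 * out.values)

    def test_requires_absorbance(self):
        s = toy_set([[50.0, 60.0, 70.0]], mode=fc.TRANSMITTANCE)
        with pytest.raises(SpectraError):
            fc.atr_correct(s)


class TestAirPLS:
    def test_pure_line_fully_removed(self):
        grid = fc.DEFAULT_GRID
        line = 0.5 + 1e-4 * (grid - 600.0)
        baseline, corrected = airpls(toy_set([line], grid=grid))
        assert np.abs(corrected.values).max() < 1e-6

    def test_recovers_known_linear_baseline_under_peaks(self):
        grid = fc.DEFAULT_GRID
        peaks = sum(a * np.exp(-0.5 * ((grid - c) / s) ** 2)
                    for c, s, a in [(2900, 15, 0.5), (1600, 20, 0.8),
                                    (1050, 20, 1.0), (800, 10, 0.3)])
        true = 0.3 + 0.1 * (grid - 600.0) / 3400.0
        baseline, corrected = airpls(toy_set([peaks + true], grid=grid))
        n = grid.size
        interior = slice(int(0.05 * n), int(0.95 * n))
        rmse = np.sqrt(np.mean(
            (baseline.values[0, interior] - true[interior]) ** 2))
        assert rmse < 0.05 * true.max()

    def test_additivity_is_exact(self):
        s = toy_set(RNG.uniform(0.0, 1.0, (3, 200)))
        baseline, corrected = airpls(s)
        np.testing.assert_allclose(baseline.values + corrected.values,
                                   s.values, rtol=0, atol=1e-12)

    def test_baseline_stays_below_peaks(self):
        # residuals above the baseline dominate on peaked data
        grid = fc.DEFAULT_GRID
        noise_sd = 0.005
        rng = np.random.default_rng(5)
        rows = []
        for _ in range(5):
            y = sum(a * np.exp(-0.5 * ((grid - c) / s) ** 2)
                    for c, s, a in [(1600, 20, 0.8), (1050, 20, 1.0)])
            rows.append(y + 0.2 + rng.normal(0, noise_sd, grid.size))
        baseline, corrected = airpls(toy_set(rows, grid=grid))
        frac_below = np.mean(corrected.values < -3 * noise_sd)
        assert frac_below < 0.01

    def test_param_validation(self):
        with pytest.raises(SpectraError):
            AirPLSParams(lam=-1)
        with pytest.raises(SpectraError):
            AirPLSParams(diff_order=3)
        with pytest.raises(SpectraError):
            AirPLSParams(tol=2.0)


class TestRecipes:
    def test_none_preset_is_absorbance_only(self, small_train):
        out = fc.apply_recipe("none", small_train)
        np.testing.assert_allclose(
            out.values, fc.to_absorbance(small_train).values)

    def test_vector_first_matches_manual_composition(self, small_train):
        out = fc.apply_recipe("vector_first", small_train)
        manual = fc.vector_normalize(
            fc.savitzky_golay(fc.to_absorbance(small_train), window=9,
                              polyorder=2, deriv=1))
        np.testing.assert_allclose(out.values, manual.values)

    def test_area_preset_includes_atr_correction(self, small_train):
        out = fc.apply_recipe("area", small_train)
        manual = fc.area_normalize(
            fc.atr_correct(fc.to_absorbance(small_train)))
        np.testing.assert_allclose(out.values, manual.values)

    def test_unknown_names_rejected(self):
        with pytest.raises(SpectraError):
            fc.preset_recipe("nope")
        with pytest.raises(SpectraError):
            fc.PreprocessRecipe(steps=[("nope", {})])

    def test_row_independence_under_permutation(self, small_train):
        perm = list(np.random.default_rng(3).permutation(
            small_train.n_samples))
        for name in ("snv", "sg", "vector_first", "airpls"):
            a = fc.apply_recipe(name, small_train.take(perm))
            b = fc.apply_recipe(name, small_train).take(perm)
            np.testing.assert_allclose(a.values, b.values, atol=1e-10,
                                       err_msg=name)

    def test_fitted_recipe_freezes_msc_reference(self, small_train):
        cal = small_train.take(range(0, 30))
        frozen = fc.preset_recipe("msc").fit(cal)
        assert frozen.n_fit_rows_ == 30
        ref = frozen.states[1]
        np.testing.assert_allclose(
            ref, fc.to_absorbance(cal).values.mean(axis=0))
        # transforming other data reuses the calibration reference
        other = small_train.take(range(30, 40))
        out = frozen.transform(other)
        manual = fc.msc(fc.to_absorbance(other), reference=ref)
        np.testing.assert_allclose(out.values, manual.values)
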