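"""KDE border estimator: bandwidth, densities, comparison, read-out."""

import numpy as np
import pandas as pd
import pytest

from prfscotoma.kde import (
    ComparisonCurve,
    classify_border,
    comparison_curve,
    estimate_border,
    gated_eccentricities,
    group_average,
    kde_curve,
    scotts_bandwidth,
)


class TestScottsBandwidth:
    def test_direct_evaluation(self):
        assert scotts_bandwidth(2.0, 1000) == pytest.approx(0.7, abs=1e-12)
        assert scotts_bandwidth(1.0, 1) == 3.5

    def test_linearity_in_sigma(self):
        assert scotts_bandwidth(2.4, 57) == pytest.approx(
            2 * scotts_bandwidth(1.2, 57), rel=1e-12
        )

    @pytest.mark.parametrize("sigma,n", [(0.0, 10), (-1.0, 10), (1.0, 0)])
    def test_domain_errors(self, sigma, n):
        with pytest.raises(ValueError):
            scotts_bandwidth(sigma, n)


class TestKDECurve:
    def test_single_center_peak_value(self):
        """Closed form: a unit Gaussian density with sd 0.5 peaks at
        1/√(2π·0.25) ≈ 0.7979."""
        grid = np.arange(0, 8.0001, 0.01)
        curve = kde_curve([3.0], eval_grid=grid, w_override=0.5)
        peak_idx = np.argmax(curve.density)
        assert grid[peak_idx] == pytest.approx(3.0)
        assert curve.density[peak_idx] == pytest.approx(
            1 / np.sqrt(2 * np.pi * 0.25), rel=1e-9
        )

    def test_integrates_to_one_on_wide_grid(self):
        rng = np.random.default_rng(2)
        ecc = rng.uniform(1, 6, 500)
        grid = np.arange(-12.0, 20.0001, 0.005)
        curve = kde_curve(ecc, eval_grid=grid)
        assert curve.integral() == pytest.approx(1.0, abs=1e-6)

    def test_symmetry_of_two_centers(self):
        grid = np.arange(0, 6.0001, 0.01)
        curve = kde_curve([2.0, 4.0], eval_grid=grid, w_override=0.4)
        d = curve.density
        mid = np.argmin(np.abs(grid - 3.0))
        assert np.allclose(d[: mid + 1], d[mid:][::-1], atol=1e-12)

    def test_bandwidth_invariant(self):
        rng = np.random.default_rng(5)
        curve = kde_curve(rng.uniform(0, 7, 200))
        assert curve.bandwidth_w == scotts_bandwidth(curve.sigma_r, curve.n_centers)

    def test_empty_source_rejected(self):
        with pytest.raises(ValueError):
            kde_curve([])


class TestComparisonCurve:
    def test_identical_curves_give_zero(self):
        grid = np.arange(0, 8.0001, 0.01)
        a = kde_curve([1.0, 2.0, 3.0], eval_grid=grid, w_override=0.5)
        comp = comparison_curve(a, a)
        defined = np.isfinite(comp.value)
        assert np.allclose(comp.value[defined], 0.0)

    def test_pure_reference_surplus_is_one(self):
        """Where the scotoma condition has no centers at all, the
        normalized difference saturates at +1."""
        grid = np.arange(0, 8.0001, 0.01)
        ref = kde_curve([1.0], eval_grid=grid, w_override=0.3)
        scot = kde_curve([7.5], eval_grid=grid, w_override=0.3)
        comp = comparison_curve(ref, scot)
        near_one = np.isfinite(comp.value) & (grid < 1.5)
        assert np.all(comp.value[near_one] > 0.999)

    def test_bounded_wherever_defined(self):
        rng = np.random.default_rng(9)
        grid = np.arange(0, 8.0001, 0.01)
        ref = kde_curve(rng.uniform(0, 7, 300), eval_grid=grid)
        scot = kde_curve(rng.uniform(2, 7, 200), eval_grid=grid)
        comp = comparison_curve(ref, scot)
        v = comp.value[np.isfinite(comp.value)]
        assert np.all(np.abs(v) <= 1.0 + 1e-12)

    def test_peripheral_scotoma_surplus_is_negative(self):
        grid = np.arange(0, 8.0001, 0.01)
        ref = kde_curve(np.linspace(0, 7, 100), eval_grid=grid)
        scot = kde_curve(np.linspace(2.2, 7, 100), eval_grid=grid)
        comp = comparison_curve(ref, scot)
        sel = (grid > 3) & (grid < 6) & np.isfinite(comp.value)
        assert comp.value[sel].min() < 0

    def test_grid_mismatch_rejected(self):
        a = kde_curve([1.0], eval_grid=np.arange(0, 8, 0.01), w_override=0.5)
        b = kde_curve([1.0], eval_grid=np.arange(0, 7, 0.01), w_override=0.5)
        with pytest.raises(ValueError):
            comparison_curve(a, b)


def _comp(x, v):
    return ComparisonCurve(eval_ecc=np.asarray(x, float), value=np.asarray(v, float))


class TestBorderReadout:
    def test_analytic_interpolation(self):
        """Piecewise-linear curve crossing 0.1 exactly at x = 1.5."""
        comp = _comp([0, 1, 2], [0.5, 0.2, 0.0])
        assert estimate_border(comp) == pytest.approx(1.5, abs=1e-12)

    def test_no_scotoma_flag(self):
        comp = _comp([0, 1, 2], [-0.2, 0.0, -0.4])
        border, status = classify_border(comp)
        assert border is None and status == "no_scotoma"

    def test_non_central_pattern_flag(self):
        comp = _comp([0, 1, 2, 3], [0.0, 0.5, 0.5, 0.0])
        border, status = classify_border(comp)
        assert border is None and status == "non_central"

    def test_entirely_undefined_curve_rejected(self):
        comp = _comp([0, 1], [np.nan, np.nan])
        with pytest.raises(ValueError):
            classify_border(comp)


class TestGroupAverage:
    def test_single_curve_identity(self):
        curve = kde_curve([1.0, 2.0], w_override=0.5)
        avg = group_average([curve])
        assert np.allclose(avg.density, curve.density)

    def test_pointwise_mean(self):
        a = kde_curve([1.0], w_override=0.5)
        b = kde_curve([3.0], w_override=0.5)
        avg = group_average([a, b])
        assert np.allclose(avg.density, (a.density + b.density) / 2)

    def test_averaged_curve_border_differs_from_subject_mean(self):
        """Constructed two-subject example: individual borders at 1.8
        and ≈2.19, but the averaged classification curve crosses the
        threshold at neither value nor at their mean."""
        x = np.arange(0, 4.0001, 0.01)
        a = _comp(x, 0.28 - 0.1 * x)  # shallow fall, crosses 0.1 at 1.8
        b = _comp(x, np.where(x < 2.15, 1.0, 1.0 - 9.0 * (x - 2.15)))  # steep
        border_a = estimate_border(a)
        border_b = estimate_border(b)
        assert border_a == pytest.approx(1.8, abs=1e-9)
        avg = group_average([a, b])
        border_avg = estimate_border(avg)
        assert border_avg is not None
        assert abs(border_avg - (border_a + border_b) / 2) > 0.05

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            group_average([])


def test_gated_eccentricities_filter():
    table = pd.DataFrame(
        {
            "eccentricity": [1.0, 2.0, 3.0, 4.0],
            "variance_explained": [0.05, 0.2, np.nan, 0.5],
        }
    )
    assert list(gated_eccentricities(table, 0.10)) == [2.0, 4.0]
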