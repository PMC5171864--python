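"""Time-course models: quadratic fits, segmental regression with
breakpoint search, the P2 standard curve and effect classification."""

import numpy as np
import pytest

import finquant as fq
from finquant.exceptions import (
    NoBreakpointError,
    SingularFitError,
    UnderpoweredError,
    WindowTooSparseError,
)
from finquant.phase_model import (
    REFERENCE_X0,
    SegmentalRegression,
    StandardCurve,
    classify_effect,
    fit_poly2,
)


def _segmental_data(x, x0=0.6, a=0.0, b=0.0, c=1.2, noise=0.0, rng=None):
    x = np.asarray(x, float)
    y = a + b * np.minimum(x, x0) + c * np.maximum(x - x0, 0.0)
    if noise and rng is not None:
        y = y + rng.normal(0, noise, x.size)
    return x, y


def _fine_grid_oracle(x, y, step=0.001):
    """Exhaustive fine-grid breakpoint search (independent of the fit)."""
    best = (np.inf, None)
    for x0 in np.arange(x.min() + step, x.max(), step):
        if (x <= x0).sum() < 3 or (x > x0).sum() < 3:
            continue
        X = np.column_stack([np.ones_like(x), x, np.maximum(x - x0, 0)])
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(((y - X @ coef) ** 2).sum())
        if sse < best[0] - 1e-15:
            best = (sse, float(x0))
    return best


class TestPoly2:
    def test_exact_interpolation_of_square(self):
        fit = fit_poly2([0, 1, 2], [0, 1, 4])
        assert (fit.c0, fit.c1, fit.c2) == pytest.approx((0, 0, 1), abs=1e-12)
        assert fit.sse == pytest.approx(0, abs=1e-20)

    def test_constant_series_has_zero_curvature(self):
        fit = fit_poly2([0, 1, 2, 3], [5, 5, 5, 5])
        assert fit.c1 == pytest.approx(0, abs=1e-12)
        assert fit.c2 == pytest.approx(0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        t = rng.uniform(0, 10, 60)
        y = rng.normal(size=60)
        fit = fit_poly2(t, y)
        X = np.vander(t, 3, increasing=True)
        ref = np.linalg.solve(X.T @ X, X.T @ y)
        assert [fit.c0, fit.c1, fit.c2] == pytest.approx(list(ref), abs=1e-8)

    def test_degenerate_abscissae_rejected(self):
        with pytest.raises(SingularFitError):
            fit_poly2([1, 1, 1, 2], [0, 1, 2, 3])


class TestSegmentalRegression:
    def test_noiseless_model_recovered_exactly(self):
        x = np.linspace(0, 1.2, 24)
        x, y = _segmental_data(x, x0=0.6, b=0.0, c=1.2)
        fit = SegmentalRegression(x, y).fit()
        assert fit.x0 == pytest.approx(0.6, abs=1e-3)
        assert fit.b == pytest.approx(0.0, abs=1e-6)
        assert fit.c == pytest.approx(1.2, abs=1e-3)
        assert fit.sse == pytest.approx(0.0, abs=1e-10)

    def test_single_line_flagged_unidentifiable(self):
        x = np.linspace(0, 1, 12)
        y = 0.3 + 0.7 * x
        fit = SegmentalRegression(x, y).fit()
        from scipy.stats import linregress

        lr = linregress(x, y)
        sse_line = float(((y - (lr.intercept + lr.slope * x)) ** 2).sum())
        assert fit.sse == pytest.approx(sse_line, abs=1e-12)
        assert not fit.x0_identifiable

    def test_sse_never_exceeds_one_segment_fit(self, rng):
        for _ in range(10):
            x = rng.uniform(0, 2, 20)
            y = rng.normal(size=20)
            fit = SegmentalRegression(x, y).fit()
            assert fit.sse <= fit.sse_one_segment + 1e-10

    def test_phase_labels_partition_at_breakpoint(self, rng):
        x = rng.uniform(0, 2, 30)
        _, y = _segmental_data(x, noise=0.05, rng=rng)
        fit = SegmentalRegression(x, y).fit()
        assert set(fit.phase_labels) <= {"P1", "P2"}
        assert ((x <= fit.x0) == (fit.phase_labels == "P1")).all()

    def test_profile_search_equals_fine_grid_oracle(self, rng):
        x = np.sort(rng.uniform(0, 2, 40))
        _, y = _segmental_data(x, x0=0.9, b=0.1, c=1.0, noise=0.05, rng=rng)
        fit = SegmentalRegression(x, y).fit()
        sse_grid, x0_grid = _fine_grid_oracle(x, y)
        assert fit.sse <= sse_grid + 1e-9
        assert fit.x0 == pytest.approx(x0_grid, abs=2e-3)

    def test_cohort_breakpoint_recovered(self):
        df = fq.simulate_cohort(fq.CohortSpec(seed=11))
        fit = SegmentalRegression.from_dataframe(df).fit()
        assert fit.x0 == pytest.approx(0.586, abs=0.05)

    def test_recovery_error_grows_with_noise(self):
        """Median breakpoint error degrades monotonically with noise."""
        medians = []
        for noise in (0.02, 0.08, 0.25):
            errs = []
            for s in range(15):
                df = fq.simulate_cohort(fq.CohortSpec(seed=500 + s,
                                                      noise_cv=noise))
                fit = SegmentalRegression.from_dataframe(df).fit()
                errs.append(abs(fit.x0 - 0.586))
            medians.append(np.median(errs))
        assert medians[0] <= medians[1] <= medians[2]

    def test_too_few_points_rejected(self):
        with pytest.raises(NoBreakpointError):
            SegmentalRegression([0, 1, 2], [0, 0, 1]).fit()

    def test_constrain_b0_forces_flat_first_segment(self, rng):
        x = np.sort(rng.uniform(0, 2, 40))
        _, y = _segmental_data(x, x0=0.6, b=0.0, c=1.0, noise=0.03, rng=rng)
        fit = SegmentalRegression(x, y).fit(constrain_b0=True)
        assert fit.b == 0.0

    def test_reference_breakpoint_constant(self):
        assert REFERENCE_X0 == 0.5860


class TestStandardCurve:
    def test_collinear_points_give_r_one(self):
        t = np.linspace(90, 230, 12)
        x = np.linspace(0.8, 2.0, 12)
        y = 0.35 * (x - 0.586)
        curve = StandardCurve(x, y, t).fit()
        assert curve.r == pytest.approx(1.0)
        assert curve.slope == pytest.approx(0.35)
        assert np.allclose(curve.residuals(x, y), 0, atol=1e-12)

    def test_points_outside_window_are_ignored(self):
        t = np.linspace(90, 230, 12)
        x = np.linspace(0.8, 2.0, 12)
        y = 0.35 * (x - 0.586)
        base = StandardCurve(x, y, t).fit()
        t2 = np.concatenate([t, [24, 24, 260]])
        x2 = np.concatenate([x, [5.0, 6.0, 7.0]])
        y2 = np.concatenate([y, [0.0, 9.0, 9.0]])
        with_extra = StandardCurve(x2, y2, t2).fit()
        assert with_extra.slope == pytest.approx(base.slope)
        assert with_extra.intercept == pytest.approx(base.intercept)
        assert with_extra.n == base.n

    def test_sparse_window_rejected(self):
        with pytest.raises(WindowTooSparseError):
            StandardCurve([1, 2], [0, 1], [100, 120]).fit()

    def test_cohort_slope_recovered(self):
        df = fq.simulate_cohort(fq.CohortSpec(seed=21))
        curve = StandardCurve.from_dataframe(df).fit()
        assert curve.slope == pytest.approx(0.35, rel=0.10)
        assert curve.r > 0.9


class TestClassifyEffect:
    def _curve(self):
        x = np.linspace(0.7, 2.0, 20)
        t = np.linspace(90, 230, 20)
        return StandardCurve(x, 0.35 * (x - 0.586), t).fit()

    def test_identical_groups_called_neutral(self, rng):
        curve = self._curve()
        x = rng.normal(1.5, 0.05, 10)
        y = curve.predict(x) + rng.normal(0, 0.01, 10)
        call = classify_effect(x, y, x, y, curve)
        assert (call.regen_shift, call.mineral_shift) == ("none", "none")

    def test_antisymmetry_under_group_swap(self, rng):
        curve = self._curve()
        cx = rng.normal(1.5, 0.05, 10)
        cy = curve.predict(cx) + rng.normal(0, 0.01, 10)
        tx = rng.normal(1.0, 0.05, 10)  # under-regenerated
        ty = curve.predict(tx) + 0.08 + rng.normal(0, 0.01, 10)  # over-min.
        fwd = classify_effect(tx, ty, cx, cy, curve)
        rev = classify_effect(cx, cy, tx, ty, curve)
        assert fwd.dx == pytest.approx(-rev.dx)
        assert fwd.dy == pytest.approx(-rev.dy)
        assert (fwd.regen_shift, rev.regen_shift) == ("under", "over")
        assert (fwd.mineral_shift, rev.mineral_shift) == ("over", "under")

    def test_small_groups_rejected(self):
        curve = self._curve()
        with pytest.raises(UnderpoweredError):
            classify_effect([1, 2], [0, 0], [1, 2, 3], [0, 0, 0], curve)
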