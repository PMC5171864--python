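"""Time-course models of fin regeneration and mineralization.

The mineralized corrected area RMA/RAY is modelled as a continuous
two-segment ("segmental") linear function of the regenerated corrected
area REG/STU.  The breakpoint X0 separates phase P1 (outgrowth without
effective mineralization) from P2 (mineralization growing linearly with
regeneration); a late plateau phase P3 falls beyond the observed window
and is never fitted.  Within P2, restricted to the 84-240 hpa screening
window, an ordinary linear regression of RMA/RAY on REG/STU is the
standard curve against which treated groups are compared: displacement
*along* the curve is a regenerative effect, displacement *off* the
curve a mineralogenic one.

Model classes follow the statsmodels idiom: construct from data, call
``fit()``, inspect the returned results object (``summary()``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .exceptions import (
    NoBreakpointError,
    SingularFitError,
    UnderpoweredError,
    WindowTooSparseError,
)
from .stats import ALPHA, TestResult, pearson, t_test_unpaired

#: Breakpoint (REG/STU, mm) of the reference 60-specimen fixed-sample fit,
#: kept for plot overlays and as the default x0-based P2 gate.
REFERENCE_X0 = 0.5860

#: Screening window (hpa) within which mineralization tracks regeneration
#: linearly; points beyond it belong to P3 and are excluded.
DEFAULT_WINDOW = (84.0, 240.0)


@dataclass(frozen=True)
class Poly2Fit:
    """Least-squares degree-2 polynomial fit y = c0 + c1 t + c2 t^2."""

    c0: float
    c1: float
    c2: float
    sse: float
    n: int

    def predict(self, t):
        t = np.asarray(t, float)
        return self.c0 + self.c1 * t + self.c2 * t * t


def fit_poly2(t: Sequence[float], y: Sequence[float]) -> Poly2Fit:
    """Degree-2 polynomial least squares (exact through 3 distinct points)."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if t.size != y.size or t.size < 3:
        raise SingularFitError("need n >= 3 paired points")
    if np.unique(t).size < 3:
        raise SingularFitError("need >= 3 distinct abscissae for a quadratic")
    X = np.column_stack([np.ones_like(t), t, t * t])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:
        raise SingularFitError("rank-deficient quadratic design")
    resid = y - X @ coef
    return Poly2Fit(*map(float, coef), sse=float(resid @ resid), n=int(t.size))


def _segmental_design(x: np.ndarray, x0: float, constrain_b0: bool) -> np.ndarray:
    hinge = np.maximum(x - x0, 0.0)
    if constrain_b0:
        return np.column_stack([np.ones_like(x), hinge])
    return np.column_stack([np.ones_like(x), x, hinge])


def _segmental_sse(x: np.ndarray, y: np.ndarray, x0: float, constrain_b0: bool):
    X = _segmental_design(x, x0, constrain_b0)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), coef


class SegmentalRegression:
    """Continuous two-segment linear model of y on x.

    y = a + b x              for x <= x0
    y = a + b x0 + c (x-x0)  for x >  x0

    The breakpoint is profiled over every interior data abscissa and the
    midpoints between consecutive abscissae (each candidate solved by
    least squares), optionally refined by bounded scalar minimization
    between the bracketing candidates; ties break toward the smaller x0.

    Parameters
    ----------
    x, y : array-like
        Observations (n >= 6); typically REG/STU and RMA/RAY in mm.
    """

    def __init__(self, x: Sequence[float], y: Sequence[float]):
        self.x = np.asarray(x, float)
        self.y = np.asarray(y, float)
        if self.x.size != self.y.size or self.x.size < 6:
            raise NoBreakpointError("segmental regression needs n >= 6 paired points")

    @classmethod
    def from_dataframe(cls, df, x: str = "reg_over_stu_mm", y: str = "rma_over_ray_mm"):
        return cls(df[x].to_numpy(float), df[y].to_numpy(float))

    def _candidates(self, min_points: int) -> np.ndarray:
        xs = np.unique(self.x)
        cands = np.concatenate([xs, (xs[:-1] + xs[1:]) / 2]) if xs.size > 1 else xs
        cands = np.sort(cands)
        ok = [
            c
            for c in cands
            if (self.x <= c).sum() >= min_points and (self.x > c).sum() >= min_points
        ]
        return np.asarray(ok, float)

    def fit(
        self,
        constrain_b0: bool = False,
        refine: bool = True,
        min_points: int = 3,
    ) -> "SegmentalRegressionResults":
        """Profile-search least squares over candidate breakpoints.

        ``constrain_b0`` forces the first segment flat (b = 0), matching
        the visual flatness of the pre-mineralization phase.
        """
        x, y = self.x, self.y
        cands = self._candidates(min_points)
        if cands.size == 0:
            raise NoBreakpointError(
                f"no candidate breakpoint leaves >= {min_points} points per segment"
            )
        best_x0, best_sse, best_coef = None, math.inf, None
        for c in cands:
            sse, coef = _segmental_sse(x, y, c, constrain_b0)
            if sse < best_sse - 1e-15:
                best_x0, best_sse, best_coef = float(c), sse, coef
        if refine and cands.size > 1:
            i = int(np.searchsorted(cands, best_x0))
            lo = cands[max(i - 1, 0)]
            hi = cands[min(i + 1, cands.size - 1)]
            if hi > lo:
                res = optimize.minimize_scalar(
                    lambda c: _segmental_sse(x, y, c, constrain_b0)[0],
                    bounds=(lo, hi),
                    method="bounded",
                    options={"xatol": 1e-6},
                )
                r_sse, r_coef = _segmental_sse(x, y, float(res.x), constrain_b0)
                if r_sse < best_sse - 1e-15 and (
                    (x <= res.x).sum() >= min_points and (x > res.x).sum() >= min_points
                ):
                    best_x0, best_sse, best_coef = float(res.x), r_sse, r_coef
        if constrain_b0:
            a, b, hinge_slope = float(best_coef[0]), 0.0, float(best_coef[1])
            c_slope = hinge_slope
        else:
            a, b = float(best_coef[0]), float(best_coef[1])
            c_slope = b + float(best_coef[2])
        # One-segment (simple linear) reference for identifiability.
        X1 = np.column_stack([np.ones_like(x), x])
        coef1, _, _, _ = np.linalg.lstsq(X1, y, rcond=None)
        sse_line = float(((y - X1 @ coef1) ** 2).sum())
        identifiable = (sse_line - best_sse) > 1e-10 * max(1.0, sse_line)
        labels = np.where(x <= best_x0, "P1", "P2")
        return SegmentalRegressionResults(
            model=self,
            x0=best_x0,
            a=a,
            b=b,
            c=c_slope,
            sse=float(best_sse),
            n=int(x.size),
            phase_labels=labels,
            sse_one_segment=sse_line,
            x0_identifiable=bool(identifiable),
            constrained_b0=constrain_b0,
        )


@dataclass
class SegmentalRegressionResults:
    """Fitted continuous two-segment regression.

    ``x0`` is the P1/P2 breakpoint on the x (REG/STU) axis; ``b`` and
    ``c`` are the P1 and P2 slopes; continuity at the breakpoint is
    built into the parameterization.  ``x0_identifiable`` is False when
    the two-segment fit does not improve on a single line.
    """

    model: SegmentalRegression
    x0: float
    a: float
    b: float
    c: float
    sse: float
    n: int
    phase_labels: np.ndarray
    sse_one_segment: float
    x0_identifiable: bool
    constrained_b0: bool = False

    def predict(self, x):
        x = np.asarray(x, float)
        return self.a + self.b * np.minimum(x, self.x0) + self.c * np.maximum(
            x - self.x0, 0.0
        )

    def summary(self) -> str:
        lines = [
            "Segmental linear regression (continuous two-segment)",
            f"  n observations      : {self.n}",
            f"  breakpoint X0       : {self.x0:.4f}",
            f"  P1 intercept (a)    : {self.a:.4f}",
            f"  P1 slope (b)        : {self.b:.4f}"
            + ("  [constrained 0]" if self.constrained_b0 else ""),
            f"  P2 slope (c)        : {self.c:.4f}",
            f"  SSE                 : {self.sse:.6g}",
            f"  SSE one-segment ref : {self.sse_one_segment:.6g}",
            f"  X0 identifiable     : {self.x0_identifiable}",
            f"  points in P1 / P2   : {(self.phase_labels == 'P1').sum()}"
            f" / {(self.phase_labels == 'P2').sum()}",
        ]
        return "\n".join(lines)


class StandardCurve:
    """P2 standard curve: OLS of RMA/RAY on REG/STU inside the screening
    window (default 84-240 hpa).

    Parameters
    ----------
    reg_over_stu, rma_over_ray, time_hpa : array-like
        The control-cohort corrected metrics with their sampling times.
    window : (t_min, t_max)
        Screening window in hpa.
    """

    def __init__(
        self,
        reg_over_stu: Sequence[float],
        rma_over_ray: Sequence[float],
        time_hpa: Sequence[float],
        window: tuple[float, float] = DEFAULT_WINDOW,
    ):
        self.x = np.asarray(reg_over_stu, float)
        self.y = np.asarray(rma_over_ray, float)
        self.t = np.asarray(time_hpa, float)
        if not (self.x.size == self.y.size == self.t.size):
            raise WindowTooSparseError("mismatched series lengths")
        self.window = (float(window[0]), float(window[1]))

    @classmethod
    def from_dataframe(cls, df, window: tuple[float, float] = DEFAULT_WINDOW):
        return cls(
            df["reg_over_stu_mm"].to_numpy(float),
            df["rma_over_ray_mm"].to_numpy(float),
            df["time_hpa"].to_numpy(float),
            window=window,
        )

    def fit(self, min_points: int = 10) -> "StandardCurveResults":
        t0, t1 = self.window
        sel = (self.t >= t0) & (self.t <= t1)
        if int(sel.sum()) < min_points:
            raise WindowTooSparseError(
                f"only {int(sel.sum())} points inside window {self.window}; "
                f"need >= {min_points}"
            )
        x, y = self.x[sel], self.y[sel]
        n = x.size
        mx, my = float(x.mean()), float(y.mean())
        sxx = float(((x - mx) ** 2).sum())
        if sxx == 0:
            raise WindowTooSparseError("degenerate abscissae inside window")
        slope = float(((x - mx) * (y - my)).sum() / sxx)
        intercept = my - slope * mx
        resid = y - (intercept + slope * x)
        sse = float(resid @ resid)
        syy = float(((y - my) ** 2).sum())
        r = 1.0 if syy == 0 else float(np.sign(slope) * math.sqrt(max(0.0, 1 - sse / syy)))
        resid_std = math.sqrt(sse / (n - 2)) if n > 2 else 0.0
        return StandardCurveResults(
            slope=slope,
            intercept=intercept,
            r=r,
            n=int(n),
            window=self.window,
            mean_x=mx,
            sxx=sxx,
            resid_std=resid_std,
        )


@dataclass(frozen=True)
class StandardCurveResults:
    """Fitted P2 standard curve with 95% prediction-band parameters."""

    slope: float
    intercept: float
    r: float
    n: int
    window: tuple[float, float]
    mean_x: float
    sxx: float
    resid_std: float

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, float)

    def residuals(self, x, y):
        return np.asarray(y, float) - self.predict(x)

    def prediction_halfwidth(self, x, alpha: float = ALPHA):
        """Half-width of the (1-alpha) prediction band at x (for flagging
        single specimens, not group comparisons)."""
        from scipy import stats as sps

        x = np.asarray(x, float)
        se = self.resid_std * np.sqrt(
            1 + 1 / self.n + (x - self.mean_x) ** 2 / self.sxx
        )
        return float(sps.t.ppf(1 - alpha / 2, self.n - 2)) * se

    def summary(self) -> str:
        return "\n".join(
            [
                "P2 standard curve (OLS of RMA/RAY on REG/STU)",
                f"  window (hpa)  : {self.window[0]:g}-{self.window[1]:g}",
                f"  n             : {self.n}",
                f"  slope         : {self.slope:.4f}",
                f"  intercept     : {self.intercept:.4f}",
                f"  Pearson r     : {self.r:.4f}",
                f"  resid std     : {self.resid_std:.4g}",
            ]
        )


@dataclass(frozen=True)
class EffectCall:
    """Classification of a treated group against the control standard curve.

    ``dx`` is the treated-minus-control displacement along the
    regeneration axis (REG/STU); ``dy`` the mean treated residual off
    the control curve minus the mean control residual.  Shifts are
    'none' unless the corresponding two-group t-test is significant.
    """

    regen_shift: str  # under | none | over
    mineral_shift: str
    dx: float
    dy: float
    p_dx: float
    p_dy: float
    n_treated: int
    n_control: int
    time_hpa: Optional[float] = None

    def summary(self) -> str:
        return (
            f"EffectCall(t={self.time_hpa}): regeneration {self.regen_shift} "
            f"(dx={self.dx:+.4f}, p={self.p_dx:.4g}); mineralization "
            f"{self.mineral_shift} (dy={self.dy:+.4f}, p={self.p_dy:.4g})"
        )


def _shift(value: float, p: float, alpha: float) -> str:
    if p >= alpha or value == 0:
        return "none"
    return "over" if value > 0 else "under"


def classify_effect(
    treated_reg_stu: Sequence[float],
    treated_rma_ray: Sequence[float],
    control_reg_stu: Sequence[float],
    control_rma_ray: Sequence[float],
    curve: StandardCurveResults,
    alpha: float = ALPHA,
    time_hpa: Optional[float] = None,
) -> EffectCall:
    """Call regenerative / mineralogenic shifts at one nominal time point.

    dx: unpaired t-test on REG/STU (along-curve displacement).
    dy: unpaired t-test on residuals from the control standard curve
    (off-curve displacement).
    """
    tx = np.asarray(treated_reg_stu, float)
    ty = np.asarray(treated_rma_ray, float)
    cx = np.asarray(control_reg_stu, float)
    cy = np.asarray(control_rma_ray, float)
    if min(tx.size, cx.size) < 3:
        raise UnderpoweredError("need >= 3 specimens per group")
    t_res = curve.residuals(tx, ty)
    c_res = curve.residuals(cx, cy)
    dx = float(tx.mean() - cx.mean())
    dy = float(t_res.mean() - c_res.mean())
    test_dx = t_test_unpaired(tx, cx)
    test_dy = t_test_unpaired(t_res, c_res)
    return EffectCall(
        regen_shift=_shift(dx, test_dx.p_value, alpha),
        mineral_shift=_shift(dy, test_dy.p_value, alpha),
        dx=dx,
        dy=dy,
        p_dx=test_dx.p_value,
        p_dy=test_dy.p_value,
        n_treated=int(tx.size),
        n_control=int(cx.size),
        time_hpa=time_hpa,
    )


def consensus_call(calls: Sequence[EffectCall]) -> EffectCall:
    """Combine per-time-point calls into one screening verdict.

    A shift is called only when every assayed time point shows the same
    significant direction; this replication requirement keeps the
    familywise false-call rate of a multi-time-point screen low.  The
    reported dx/dy are means over time points and p-values the maxima
    (the weakest link).
    """
    if not calls:
        raise UnderpoweredError("no per-time-point calls to combine")
    regen = {c.regen_shift for c in calls}
    mineral = {c.mineral_shift for c in calls}
    return EffectCall(
        regen_shift=regen.pop() if len(regen) == 1 else "none",
        mineral_shift=mineral.pop() if len(mineral) == 1 else "none",
        dx=float(np.mean([c.dx for c in calls])),
        dy=float(np.mean([c.dy for c in calls])),
        p_dx=float(max(c.p_dx for c in calls)),
        p_dy=float(max(c.p_dy for c in calls)),
        n_treated=int(sum(c.n_treated for c in calls)),
        n_control=int(sum(c.n_control for c in calls)),
        time_hpa=None,
    )


def correlation_with_time(df, column: str) -> TestResult:
    """Pearson correlation of one measured column against time, for
    comparing the efficacy of the correction factors."""
    sub = df[["time_hpa", column]].dropna()
    return pearson(sub["time_hpa"].to_numpy(float), sub[column].to_numpy(float))
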