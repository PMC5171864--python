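"""Statistical procedures used by the pipeline: Pearson correlation,
one-way ANOVA with Tukey's HSD, unpaired Student's t and Grubbs' outlier
test.  Statistics are computed from their closed-form definitions;
p-values come from scipy's distribution objects.  Significance level is
alpha = 0.05 throughout unless overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .exceptions import UndefinedStatisticError

ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: tuple
    method: str
    extra: dict = field(default_factory=dict)


def pearson(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson product-moment correlation with a two-sided t-based p-value.

    t = r * sqrt((n-2) / (1-r^2)) with n-2 degrees of freedom.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n != y.size or n < 3:
        raise UndefinedStatisticError("pearson needs paired series with n >= 3")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = float(np.sqrt((dx**2).sum()))
    sy = float(np.sqrt((dy**2).sum()))
    if sx == 0 or sy == 0:
        raise UndefinedStatisticError("correlation undefined for a constant series")
    r = float((dx * dy).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        t, p = math.inf * math.copysign(1, r), 0.0
    else:
        t = r * math.sqrt((n - 2) / (1 - r**2))
        p = 2 * sps.t.sf(abs(t), n - 2)
    return TestResult(t, float(p), (n - 2,), "pearson", {"r": r, "r2": r**2, "n": n})


def _group_arrays(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    gs = [np.asarray(g, float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise UndefinedStatisticError("need >= 2 groups with n >= 2 each")
    return gs


def _anova_tables(gs: list[np.ndarray]):
    k = len(gs)
    ns = np.array([g.size for g in gs])
    n = int(ns.sum())
    grand = float(np.concatenate(gs).mean())
    ss_between = float(sum(g.size * (g.mean() - grand) ** 2 for g in gs))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in gs))
    df_b, df_w = k - 1, n - k
    return ss_between, ss_within, df_b, df_w, ns


def anova_oneway(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA, F = MS_between / MS_within."""
    gs = _group_arrays(groups)
    ssb, ssw, dfb, dfw, _ = _anova_tables(gs)
    msb, msw = ssb / dfb, ssw / dfw
    if msw == 0:
        if msb == 0:
            # All observations identical: no evidence either way.
            return TestResult(0.0, 1.0, (dfb, dfw), "anova_oneway", {"degenerate": True})
        return TestResult(math.inf, 0.0, (dfb, dfw), "anova_oneway", {"degenerate": True})
    f = msb / msw
    p = float(sps.f.sf(f, dfb, dfw))
    return TestResult(float(f), p, (dfb, dfw), "anova_oneway", {"ms_within": msw})


def tukey_hsd(
    groups: Sequence[Sequence[float]], labels: Optional[Sequence[str]] = None
) -> dict[tuple, TestResult]:
    """Tukey's honestly-significant-difference post hoc test.

    q_ij = |mean_i - mean_j| / sqrt(MS_within/2 * (1/n_i + 1/n_j))
    (Tukey-Kramer for unequal n); p-values from the studentized-range
    distribution with k groups and the ANOVA within-group df.
    """
    gs = _group_arrays(groups)
    k = len(gs)
    labels = list(labels) if labels is not None else list(range(k))
    _, ssw, _, dfw, ns = _anova_tables(gs)
    msw = ssw / dfw
    out: dict[tuple, TestResult] = {}
    for i, j in combinations(range(k), 2):
        diff = abs(float(gs[i].mean() - gs[j].mean()))
        se = math.sqrt(msw / 2 * (1 / ns[i] + 1 / ns[j]))
        if se == 0:
            q = 0.0 if diff == 0 else math.inf
            p = 1.0 if diff == 0 else 0.0
        else:
            q = diff / se
            p = float(np.clip(sps.studentized_range.sf(q, k, dfw), 0, 1))
        out[(labels[i], labels[j])] = TestResult(
            q, p, (k, dfw), "tukey_hsd", {"mean_diff": diff}
        )
    return out


def t_test_unpaired(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> TestResult:
    """Two-sided unpaired t-test; pooled variance by default, Welch optional.

    Zero pooled variance is handled by the limit convention: equal means
    give p = 1, unequal means give p = 0.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise UndefinedStatisticError("each sample needs n >= 2")
    na, nb = a.size, b.size
    diff = float(a.mean() - b.mean())
    va = float(a.var(ddof=1))
    vb = float(b.var(ddof=1))
    if welch:
        se2 = va / na + vb / nb
        if se2 == 0:
            return _degenerate_t(diff, (na + nb - 2,), "t_test_welch")
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        t = diff / math.sqrt(se2)
        method = "t_test_welch"
    else:
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        if sp2 == 0:
            return _degenerate_t(diff, (df,), "t_test_pooled")
        t = diff / math.sqrt(sp2 * (1 / na + 1 / nb))
        method = "t_test_pooled"
    p = 2 * float(sps.t.sf(abs(t), df))
    return TestResult(float(t), p, (float(df),), method, {"mean_diff": diff})


def _degenerate_t(diff: float, df: tuple, method: str) -> TestResult:
    if diff == 0:
        return TestResult(0.0, 1.0, df, method, {"degenerate": True, "mean_diff": diff})
    return TestResult(
        math.copysign(math.inf, diff), 0.0, df, method,
        {"degenerate": True, "mean_diff": diff},
    )


@dataclass(frozen=True)
class GrubbsResult:
    """Outcome of a single two-sided Grubbs test (no iterative removal)."""

    outlier_index: Optional[int]
    g: float
    g_critical: float
    method: str = "grubbs_two_sided"


def grubbs(x: Sequence[float], alpha: float = ALPHA) -> GrubbsResult:
    """Two-sided Grubbs test flagging at most one extreme observation.

    G = max|x_i - mean| / sd;  G_crit = ((n-1)/sqrt(n)) *
    sqrt(t^2 / (n - 2 + t^2)) with t the upper alpha/(2n) quantile of
    Student's t with n-2 df.  Ties on the extreme deviation resolve to
    the first-encountered point.  sd = 0 yields a degenerate no-outlier
    result.
    """
    x = np.asarray(x, float)
    n = x.size
    if n < 3:
        raise UndefinedStatisticError("grubbs needs n >= 3")
    sd = float(x.std(ddof=1))
    if sd == 0:
        return GrubbsResult(None, 0.0, math.inf)
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))  # first-encountered extreme on ties
    g = float(dev[idx] / sd)
    t = float(sps.t.ppf(1 - alpha / (2 * n), n - 2))
    g_crit = (n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2))
    return GrubbsResult(idx if g > g_crit else None, g, g_crit)
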