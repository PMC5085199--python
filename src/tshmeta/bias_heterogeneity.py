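"""Small-study-effect tests and heterogeneity diagnostics.

Egger's regression test, Begg's adjusted rank-correlation test, and
plot-ready coordinates for funnel and Galbraith (radial) plots.  No
figures are drawn here; the functions emit the numbers a plotting layer
or a TSV report needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats

from .effect_measures import Estimate
from .pooling import PooledResult

__all__ = [
    "EggerResult",
    "BeggResult",
    "GalbraithPoint",
    "egger_test",
    "begg_test",
    "funnel_data",
    "galbraith_data",
]


@dataclass(frozen=True)
class EggerResult:
    """Egger regression of standardized effect on precision.

    A non-zero intercept signals funnel-plot asymmetry (small-study
    effects); the slope estimates the underlying effect.
    """

    intercept: float
    intercept_se: float
    t: float
    p: float
    slope: float
    df: int


@dataclass(frozen=True)
class BeggResult:
    """Begg rank correlation between standardized deviates and variances."""

    kendall_tau: float
    p: float
    continuity_corrected: bool
    exact: bool


@dataclass(frozen=True)
class GalbraithPoint:
    """One study's radial-plot coordinates: x = 1/se, y = effect/se."""

    study_id: str
    x: float
    y: float
    residual: float
    outlier: bool


def egger_test(estimates: list[Estimate]) -> EggerResult:
    """Egger's test for small-study effects.

    Regress the standardized effect y_i/se_i on the precision 1/se_i by
    unweighted least squares and t-test the intercept against zero on
    k - 2 degrees of freedom.  (This parameterization is equivalent to
    the weighted regression of y_i on se_i.)

    Requires k >= 3 and at least two distinct standard errors,
    otherwise the two-column design is collinear.
    """
    k = len(estimates)
    if k < 3:
        raise ValueError("Egger test needs at least 3 studies (df = k - 2 >= 1)")
    se = np.array([e.se for e in estimates])
    if np.ptp(se) == 0:
        raise ValueError("all standard errors equal: precision column is collinear "
                         "with the intercept")
    z = np.array([e.y for e in estimates]) / se
    prec = 1.0 / se
    X = np.column_stack([np.ones(k), prec])
    coef, *_ = np.linalg.lstsq(X, z, rcond=None)
    resid = z - X @ coef
    df = k - 2
    s2 = float(resid @ resid) / df
    cov = s2 * np.linalg.inv(X.T @ X)
    se_int = math.sqrt(cov[0, 0])
    t = coef[0] / se_int
    p = float(2.0 * stats.t.sf(abs(t), df))
    return EggerResult(intercept=float(coef[0]), intercept_se=se_int,
                       t=float(t), p=p, slope=float(coef[1]), df=df)


def _sign_matrix(x: np.ndarray) -> np.ndarray:
    return np.sign(np.subtract.outer(x, x))


def _kendall_T(u: np.ndarray, w: np.ndarray) -> int:
    """Kendall score: concordant minus discordant pairs (ties score 0)."""
    prod = _sign_matrix(u) * _sign_matrix(w)
    return int(np.sum(np.triu(prod, 1)))


def begg_test(estimates: list[Estimate], exact_max_k: int = 8) -> BeggResult:
    """Begg's adjusted rank correlation test.

    Correlates the variance-stabilised deviates

        u_i = (y_i - y_fixed) / sqrt(v_i - 1/sum(1/v))

    with the sampling variances v_i using Kendall's tau.  For
    k <= ``exact_max_k`` the p-value is an exact permutation
    enumeration over all orderings; for larger k the tie-corrected
    normal approximation with a continuity correction is used.
    """
    k = len(estimates)
    if k < 3:
        raise ValueError("Begg test needs at least 3 studies")
    y = np.array([e.y for e in estimates])
    v = np.array([e.v for e in estimates])
    w = 1.0 / v
    y_f = float(np.sum(w * y) / np.sum(w))
    # conditional variance of y_i - y_fixed; clip guards rounding at v_i ~ 1/sum(w)
    cond = np.clip(v - 1.0 / np.sum(w), 1e-300, None)
    u = (y - y_f) / np.sqrt(cond)

    T = _kendall_T(u, v)
    n_pairs = k * (k - 1) // 2
    ties_u = _tie_counts(u)
    ties_v = _tie_counts(v)
    denom = math.sqrt((n_pairs - ties_u) * (n_pairs - ties_v))
    tau = T / denom if denom > 0 else 0.0

    if k <= exact_max_k and ties_u == 0 and ties_v == 0:
        # exact null: permute one ranking, count |T'| >= |T|
        su = _sign_matrix(u)
        sv = _sign_matrix(v)
        triu = np.triu_indices(k, 1)
        count = 0
        total = 0
        for perm in permutations(range(k)):
            total += 1
            idx = np.asarray(perm)
            Tp = int(np.sum((su * sv[np.ix_(idx, idx)])[triu]))
            if abs(Tp) >= abs(T):
                count += 1
        return BeggResult(kendall_tau=float(tau), p=count / total,
                          continuity_corrected=False, exact=True)

    var_T = _kendall_var(k, u, v)
    if var_T <= 0:
        return BeggResult(kendall_tau=0.0, p=1.0, continuity_corrected=True, exact=False)
    z = (abs(T) - 1.0) / math.sqrt(var_T)  # continuity correction
    z = max(z, 0.0)
    return BeggResult(kendall_tau=float(tau), p=float(2.0 * stats.norm.sf(z)),
                      continuity_corrected=True, exact=False)


def _tie_counts(x: np.ndarray) -> int:
    _, counts = np.unique(x, return_counts=True)
    return int(sum(c * (c - 1) // 2 for c in counts))


def _kendall_var(k: int, u: np.ndarray, v: np.ndarray) -> float:
    """Null variance of the Kendall score with tie correction."""

    def tie_term(x, f):
        _, counts = np.unique(x, return_counts=True)
        return float(sum(f(int(c)) for c in counts))

    f0 = lambda t: t * (t - 1) * (2 * t + 5)
    v0 = k * (k - 1) * (2 * k + 5)
    vt = tie_term(u, f0)
    vv = tie_term(v, f0)
    var = (v0 - vt - vv) / 18.0
    f1 = lambda t: t * (t - 1) * (t - 2)
    f2 = lambda t: t * (t - 1)
    var += (tie_term(u, f1) * tie_term(v, f1)) / (9.0 * k * (k - 1) * (k - 2))
    var += (tie_term(u, f2) * tie_term(v, f2)) / (2.0 * k * (k - 1))
    return var


def funnel_data(estimates: list[Estimate], pooled: PooledResult,
                n_line_points: int = 2) -> dict:
    """Coordinates for a funnel plot.

    Returns the per-study (y, se) points and the pseudo-95%-CI guide
    lines ``pooled y +/- 1.96 se`` evaluated from se = 0 to the largest
    observed se.  The lines meet at the pooled effect at se = 0.
    """
    if not estimates:
        raise ValueError("no estimates")
    points = [(e.study_id, e.y, e.se) for e in estimates]
    se_max = max(e.se for e in estimates)
    zq = stats.norm.ppf(0.975)
    se_grid = np.linspace(0.0, se_max, max(2, n_line_points))
    lines = {
        "lower": [(float(s), pooled.y_pooled - zq * float(s)) for s in se_grid],
        "upper": [(float(s), pooled.y_pooled + zq * float(s)) for s in se_grid],
    }
    return {"points": points, "guide_lines": lines, "pooled_y": pooled.y_pooled}


def galbraith_data(estimates: list[Estimate], threshold: float = 2.0) -> list[GalbraithPoint]:
    """Galbraith (radial) plot coordinates with outlier flags.

    Plots the standardized effect z_i = y_i/se_i against the precision
    x_i = 1/se_i, fits the no-intercept line z = b x (whose slope is
    the fixed-effect pooled estimate), and flags studies whose residual
    from that line exceeds +/- ``threshold`` (strict inequality).
    Flagged studies are the usual suspects when hunting the drivers of
    heterogeneity.
    """
    if len(estimates) < 2:
        raise ValueError("Galbraith plot needs at least 2 studies")
    se = np.array([e.se for e in estimates])
    x = 1.0 / se
    z = np.array([e.y for e in estimates]) / se
    b = float(np.sum(x * z) / np.sum(x * x))  # == fixed-effect pooled y
    out = []
    for e, xi, zi in zip(estimates, x, z):
        r = float(zi - b * xi)
        out.append(GalbraithPoint(study_id=e.study_id, x=float(xi), y=float(zi),
                                  residual=r, outlier=abs(r) > threshold))
    return out
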