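"""Fixed-effect and DerSimonian-Laird random-effects pooling.

All arithmetic stays on the analysis (log or logit) scale; the
confidence interval is back-transformed to the reporting scale at the
boundary.  Heterogeneity is summarised by Cochran's Q (computed with
fixed-effect weights), I^2 = (Q - df)/Q truncated at zero, and the
moment estimator of the between-study variance tau^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.special import expit

from .effect_measures import Estimate, log_rom
from .study_io import StudyRecord

__all__ = [
    "PooledResult",
    "pool_fixed",
    "pool_dl",
    "i_squared",
    "subgroup_pool",
    "compare_two_pooled",
    "leave_one_out",
]

_BACK_TRANSFORMS: dict[str, Callable[[float], float]] = {
    "log_rom": math.exp,
    "log_or": math.exp,
    "logit_sens": expit,
    "logit_spec": expit,
}


@dataclass
class PooledResult:
    """A pooled effect with its heterogeneity statistics.

    ``y_pooled``/``se_pooled`` are on the analysis scale; ``ci_low`` /
    ``ci_high`` (and :attr:`effect`) are back-transformed to the
    reporting scale (ratio for log measures, proportion for logits).
    """

    k: int
    y_pooled: float
    se_pooled: float
    ci_low: float
    ci_high: float
    z: float
    p_z: float
    Q: float
    df: int
    p_q: float
    i_squared: float
    tau_squared: float
    weights: dict[str, float]
    model: str
    measure: str = "log_rom"
    alpha: float = 0.05

    @property
    def effect(self) -> float:
        """Pooled effect on the reporting scale."""
        return _BACK_TRANSFORMS[self.measure](self.y_pooled)


def i_squared(Q: float, df: int) -> float:
    """I^2 = (Q - df)/Q, truncated at 0; the share of variation beyond chance."""
    if Q < 0:
        raise ValueError("Q must be non-negative")
    if df < 1:
        raise ValueError("df must be >= 1")
    if Q <= 0:
        return 0.0
    return max(0.0, (Q - df) / Q)


def _validate(estimates: Sequence[Estimate]) -> tuple[np.ndarray, np.ndarray, list[str], str]:
    if len(estimates) == 0:
        raise ValueError("cannot pool an empty list of estimates")
    measures = {e.measure for e in estimates}
    if len(measures) > 1:
        raise ValueError(f"mixed measures in one pool: {sorted(measures)}")
    y = np.array([e.y for e in estimates], dtype=float)
    v = np.array([e.v for e in estimates], dtype=float)
    if np.any(v <= 0):
        raise ValueError("all variances must be strictly positive")
    ids = [e.study_id for e in estimates]
    return y, v, ids, measures.pop()


def _assemble(y: np.ndarray, v: np.ndarray, ids: list[str], measure: str,
              tau2: float, Q: float, model: str, alpha: float) -> PooledResult:
    k = len(y)
    w = 1.0 / (v + tau2)
    y_pool = float(np.sum(w * y) / np.sum(w))
    se = float(math.sqrt(1.0 / np.sum(w)))
    zq = stats.norm.ppf(1.0 - alpha / 2.0)
    back = _BACK_TRANSFORMS[measure]
    z = y_pool / se
    df = k - 1
    p_q = float(stats.chi2.sf(Q, df)) if df >= 1 else 1.0
    wn = w / np.sum(w)
    return PooledResult(
        k=k, y_pooled=y_pool, se_pooled=se,
        ci_low=float(back(y_pool - zq * se)), ci_high=float(back(y_pool + zq * se)),
        z=float(z), p_z=float(2.0 * stats.norm.sf(abs(z))),
        Q=float(Q), df=df, p_q=p_q,
        i_squared=i_squared(Q, df) if df >= 1 else 0.0,
        tau_squared=float(tau2),
        weights=dict(zip(ids, (float(x) for x in wn))),
        model=model, measure=measure, alpha=alpha,
    )


def _q_statistic(y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / v
    y_f = np.sum(w * y) / np.sum(w)
    return float(np.sum(w * (y - y_f) ** 2))


def pool_fixed(estimates: Sequence[Estimate], alpha: float = 0.05) -> PooledResult:
    """Inverse-variance fixed-effect pooling with Cochran's Q."""
    y, v, ids, measure = _validate(estimates)
    Q = _q_statistic(y, v) if len(y) > 1 else 0.0
    return _assemble(y, v, ids, measure, tau2=0.0, Q=Q, model="fixed", alpha=alpha)


def pool_dl(estimates: Sequence[Estimate], alpha: float = 0.05) -> PooledResult:
    """DerSimonian-Laird random-effects pooling.

    The moment estimator

        tau^2 = max(0, (Q - (k-1)) / (sum(w) - sum(w^2)/sum(w)))

    uses fixed-effect weights w = 1/v; random-effects weights are then
    1/(v + tau^2).  When Q <= k-1 the estimate truncates to zero and
    the result coincides with :func:`pool_fixed` exactly.  A single
    study is returned as itself with tau^2 = 0.
    """
    y, v, ids, measure = _validate(estimates)
    k = len(y)
    if k == 1:
        return _assemble(y, v, ids, measure, tau2=0.0, Q=0.0, model="random", alpha=alpha)
    w = 1.0 / v
    Q = _q_statistic(y, v)
    C = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (Q - (k - 1)) / C) if C > 0 else 0.0
    return _assemble(y, v, ids, measure, tau2=tau2, Q=Q, model="random", alpha=alpha)


def subgroup_pool(records: Sequence[StudyRecord], factor: str,
                  measure: Callable[[StudyRecord], Estimate] = log_rom,
                  alpha: float = 0.05) -> dict[str, PooledResult]:
    """Pool each level of a stratification factor independently.

    ``factor`` names a StudyRecord field (ethnicity, age_group, design,
    size_class, quality_score, tumour_size_class, tnm_stage,
    node_metastasis, histology).  Records with no value for the factor
    are pooled under the level ``"unknown"``.  Levels are pooled with
    :func:`pool_dl`.
    """
    if not records:
        raise ValueError("no records")
    if factor not in StudyRecord.__dataclass_fields__:
        raise ValueError(f"unknown stratification factor {factor!r}")
    groups: dict[str, list[Estimate]] = {}
    for r in records:
        level = getattr(r, factor)
        if level is None or level == "missing":
            level = "unknown"
        groups.setdefault(str(level), []).append(measure(r))
    return {level: pool_dl(ests, alpha=alpha) for level, ests in sorted(groups.items())}


def compare_two_pooled(a: PooledResult, b: PooledResult) -> tuple[float, float]:
    """Two-sample z contrast of two pooled effects on the analysis scale.

    z = (y_a - y_b) / sqrt(se_a^2 + se_b^2), two-sided normal p.
    """
    if a.measure != b.measure:
        raise ValueError("pooled results are on different measure scales")
    z = (a.y_pooled - b.y_pooled) / math.sqrt(a.se_pooled**2 + b.se_pooled**2)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def leave_one_out(estimates: Sequence[Estimate],
                  alpha: float = 0.05) -> list[tuple[str, PooledResult]]:
    """One-way sensitivity analysis: re-pool with each study omitted.

    Returns ``k`` pairs ``(omitted study_id, pool_dl of the rest)``.
    Requires k >= 3 so each re-pool still has two studies.
    """
    if len(estimates) < 3:
        raise ValueError("leave-one-out needs at least 3 studies")
    out = []
    for i, e in enumerate(estimates):
        rest = [x for j, x in enumerate(estimates) if j != i]
        out.append((e.study_id, pool_dl(rest, alpha=alpha)))
    return out
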