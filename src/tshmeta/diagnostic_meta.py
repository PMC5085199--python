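"""Cut-off-grouped diagnostic-accuracy meta-analysis.

Each study contributes a 2x2 table (TP/FP/FN/TN) of classifying thyroid
nodules as malignant by a serum TSH cut-off.  Studies are grouped by
cut-off band (< 0.5, 0.5-1.5, 1.5-2.5, > 3.5 mU/L).  Per group the
module pools sensitivity and specificity on the logit scale
(DerSimonian-Laird), pools the log likelihood ratios, classifies
clinical utility (PLR > 10 and NLR < 0.1), and fits the
Moses-Littenberg summary ROC with its area (AUSROC).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats
from scipy.special import expit, logit

from .effect_measures import Estimate
from .pooling import PooledResult, pool_dl

__all__ = [
    "DiagnosticStudy",
    "SrocSummary",
    "CUTOFF_GROUPS",
    "assign_cutoff_group",
    "sens_spec",
    "pool_logit",
    "plr_nlr",
    "lr_classify",
    "sroc_moses",
    "pool_log_lr",
]

CUTOFF_GROUPS = ("lt0.5", "0.5to1.5", "1.5to2.5", "gt3.5")


def assign_cutoff_group(cutoff: float) -> str:
    """Map a numeric TSH cut-off (mU/L) to its named band.

    Cut-offs in (2.5, 3.5] fall between the named bands and are
    rejected rather than silently assigned.
    """
    if cutoff < 0.5:
        return "lt0.5"
    if cutoff <= 1.5:
        return "0.5to1.5"
    if cutoff <= 2.5:
        return "1.5to2.5"
    if cutoff > 3.5:
        return "gt3.5"
    raise ValueError(f"cut-off {cutoff} mU/L lies in (2.5, 3.5], which belongs to no "
                     "named cut-off group")


@dataclass
class DiagnosticStudy:
    """One study's 2x2 classification table at a TSH cut-off."""

    study_id: str
    cutoff_group: str
    tp: int
    fp: int
    fn: int
    tn: int
    ethnicity: str = "missing"

    def __post_init__(self) -> None:
        if self.cutoff_group not in CUTOFF_GROUPS:
            raise ValueError(f"{self.study_id}: cutoff_group {self.cutoff_group!r} "
                             f"not in {CUTOFF_GROUPS}")
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.study_id}: {name} must be non-negative")
        if self.tp + self.fn < 1:
            raise ValueError(f"{self.study_id}: no diseased subjects (tp + fn = 0)")
        if self.fp + self.tn < 1:
            raise ValueError(f"{self.study_id}: no non-diseased subjects (fp + tn = 0)")


def _corrected_cells(s: DiagnosticStudy, correction: float = 0.5):
    """Apply the continuity correction to all four cells iff any is zero."""
    cells = (s.tp, s.fp, s.fn, s.tn)
    if min(cells) == 0:
        return tuple(c + correction for c in cells)
    return tuple(float(c) for c in cells)


def sens_spec(study: DiagnosticStudy, correction: float = 0.5
              ) -> tuple[float, float, Estimate, Estimate]:
    """Per-study sensitivity and specificity with logit-scale estimates.

    sens = tp/(tp+fn), spec = tn/(tn+fp); when any cell is zero the
    correction is added to every cell first so both proportions lie
    strictly inside (0, 1).  The logit variances are 1/tp + 1/fn and
    1/tn + 1/fp on the (corrected) cells.

    Returns ``(sens, spec, logit_sens_estimate, logit_spec_estimate)``.
    """
    tp, fp, fn, tn = _corrected_cells(study, correction)
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    est_sens = Estimate(study_id=study.study_id, y=float(logit(sens)),
                        v=1.0 / tp + 1.0 / fn, measure="logit_sens")
    est_spec = Estimate(study_id=study.study_id, y=float(logit(spec)),
                        v=1.0 / tn + 1.0 / fp, measure="logit_spec")
    return float(sens), float(spec), est_sens, est_spec


def pool_logit(values: list[Estimate], alpha: float = 0.05) -> PooledResult:
    """DerSimonian-Laird pooling of logit proportions.

    The pooled logit is back-transformed through the inverse logit, so
    :attr:`PooledResult.effect` and the CI are proportions in (0, 1).
    """
    if not values:
        raise ValueError("cannot pool an empty list")
    if not all(v.measure in ("logit_sens", "logit_spec") for v in values):
        raise ValueError("pool_logit expects logit-scale estimates")
    return pool_dl(values, alpha=alpha)


def plr_nlr(sens: float, spec: float) -> tuple[float, float]:
    """Positive and negative likelihood ratios.

    PLR = sens/(1-spec); NLR = (1-sens)/spec.  Inputs must be strictly
    inside (0, 1) — apply the continuity correction upstream.
    """
    if not (0.0 < sens < 1.0) or not (0.0 < spec < 1.0):
        raise ValueError("sens and spec must be strictly inside (0, 1)")
    return sens / (1.0 - spec), (1.0 - sens) / spec


def lr_classify(plr: float, nlr: float) -> str:
    """Clinical-utility quadrant of a likelihood-ratio pair.

    ``clinically_useful`` requires PLR > 10 AND NLR < 0.1 (strict);
    one-sided exceedances give ``confirmation_only`` (PLR > 10) or
    ``exclusion_only`` (NLR < 0.1); otherwise ``not_useful``.
    """
    if plr <= 0 or nlr <= 0:
        raise ValueError("likelihood ratios must be positive")
    high_plr = plr > 10.0
    low_nlr = nlr < 0.1
    if high_plr and low_nlr:
        return "clinically_useful"
    if high_plr:
        return "confirmation_only"
    if low_nlr:
        return "exclusion_only"
    return "not_useful"


def pool_log_lr(studies: list[DiagnosticStudy], which: str = "plr",
                correction: float = 0.5, alpha: float = 0.05) -> PooledResult:
    """DL pooling of per-study log likelihood ratios.

    Variance of the log LR by the delta method on the 2x2 cells:
    var(ln PLR) = 1/tp - 1/(tp+fn) + 1/fp - 1/(fp+tn) and the
    analogous expression for the NLR.
    """
    ests = []
    for s in studies:
        tp, fp, fn, tn = _corrected_cells(s, correction)
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        if which == "plr":
            y = math.log(sens / (1.0 - spec))
            v = 1.0 / tp - 1.0 / (tp + fn) + 1.0 / fp - 1.0 / (fp + tn)
        elif which == "nlr":
            y = math.log((1.0 - sens) / spec)
            v = 1.0 / fn - 1.0 / (tp + fn) + 1.0 / tn - 1.0 / (fp + tn)
        else:
            raise ValueError("which must be 'plr' or 'nlr'")
        ests.append(Estimate(study_id=s.study_id, y=y, v=v, measure="log_or"))
    return pool_dl(ests, alpha=alpha)


@dataclass
class SrocSummary:
    """One cut-off group's diagnostic summary (one report-table row)."""

    cutoff_group: str
    k: int
    pooled_sens: PooledResult
    pooled_spec: PooledResult
    pooled_plr: PooledResult
    pooled_nlr: PooledResult
    moses_a: float
    moses_b: float
    ausroc: float
    ausroc_ci: tuple[float, float] | None
    utility: str


def _moses_points(studies: list[DiagnosticStudy], correction: float):
    D, S = [], []
    for s in studies:
        tp, fp, fn, tn = _corrected_cells(s, correction)
        tpr = tp / (tp + fn)
        fpr = fp / (fp + tn)
        lt, lf = float(logit(tpr)), float(logit(fpr))
        D.append(lt - lf)
        S.append(lt + lf)
    return np.asarray(D), np.asarray(S)


def _fit_moses(D: np.ndarray, S: np.ndarray, weights: np.ndarray | None = None
               ) -> tuple[float, float]:
    X = np.column_stack([np.ones_like(S), S])
    if weights is None:
        coef, *_ = np.linalg.lstsq(X, D, rcond=None)
    else:
        W = np.sqrt(weights)
        coef, *_ = np.linalg.lstsq(X * W[:, None], D * W, rcond=None)
    return float(coef[0]), float(coef[1])


def sroc_curve(a: float, b: float):
    """The Moses-Littenberg summary ROC as a callable TPR(FPR).

    Inverting D = a + b S with D = logit(TPR) - logit(FPR) and
    S = logit(TPR) + logit(FPR) gives

        TPR(x) = expit( (a + (1 + b) * logit(x)) / (1 - b) )

    which runs from (0,0) to (1,1) whenever |b| < 1.
    """
    if abs(b) >= 1:
        raise ValueError("|slope| >= 1: the SROC back-transform is not monotone")

    def tpr(fpr):
        return expit((a + (1.0 + b) * logit(fpr)) / (1.0 - b))

    return tpr


def ausroc_from_coefficients(a: float, b: float) -> float:
    """Area under the SROC over the full FPR domain (0, 1) by quadrature."""
    tpr = sroc_curve(a, b)
    area, _ = integrate.quad(tpr, 0.0, 1.0, limit=200)
    return float(min(max(area, 0.0), 1.0))


def sroc_moses(studies: list[DiagnosticStudy], correction: float = 0.5,
               weighted: bool = False, n_boot: int = 2000,
               seed: int | None = 0, alpha: float = 0.05) -> SrocSummary:
    """Moses-Littenberg SROC with pooled accuracy for one cut-off group.

    Per study D = logit(TPR) - logit(FPR) and S = logit(TPR) +
    logit(FPR); the line D = a + b S is fitted by unweighted least
    squares (``weighted=True`` uses inverse-variance weights on D).
    The AUSROC integrates the back-transformed curve over FPR in (0,1);
    its CI is a nonparametric bootstrap over studies (percentile,
    ``n_boot`` resamples).  If |b| >= 1 the coefficients are still
    reported but the area is NaN.

    Requires k >= 3 studies.
    """
    if len(studies) < 3:
        raise ValueError("SROC fit needs at least 3 studies")
    groups = {s.cutoff_group for s in studies}
    if len(groups) > 1:
        warnings.warn(f"studies span several cut-off groups {sorted(groups)}; "
                      "fitting them as one", stacklevel=2)
    group = studies[0].cutoff_group if len(groups) == 1 else "mixed"

    sens_ests, spec_ests = [], []
    for s in studies:
        _, _, es, ep = sens_spec(s, correction)
        sens_ests.append(es)
        spec_ests.append(ep)
    pooled_sens = pool_logit(sens_ests, alpha=alpha)
    pooled_spec = pool_logit(spec_ests, alpha=alpha)
    pooled_plr = pool_log_lr(studies, "plr", correction, alpha=alpha)
    pooled_nlr = pool_log_lr(studies, "nlr", correction, alpha=alpha)

    D, S = _moses_points(studies, correction)
    w = None
    if weighted:
        w = np.array([1.0 / (e.v + p.v) for e, p in zip(sens_ests, spec_ests)])
    a, b = _fit_moses(D, S, w)
    if abs(b) >= 1:
        ausroc, ci = float("nan"), None
    else:
        ausroc = ausroc_from_coefficients(a, b)
        ci = None
        if n_boot and n_boot > 0:
            rng = np.random.default_rng(seed)
            k = len(studies)
            areas = []
            for _ in range(n_boot):
                idx = rng.integers(0, k, size=k)
                ab, bb = _fit_moses(D[idx], S[idx],
                                    None if w is None else w[idx])
                if abs(bb) < 1:
                    areas.append(ausroc_from_coefficients(ab, bb))
            if len(areas) >= 100:
                lo, hi = np.percentile(areas, [100 * alpha / 2, 100 * (1 - alpha / 2)])
                ci = (float(lo), float(hi))

    return SrocSummary(
        cutoff_group=group, k=len(studies),
        pooled_sens=pooled_sens, pooled_spec=pooled_spec,
        pooled_plr=pooled_plr, pooled_nlr=pooled_nlr,
        moses_a=a, moses_b=b, ausroc=ausroc, ausroc_ci=ci,
        utility=lr_classify(math.exp(pooled_plr.y_pooled), math.exp(pooled_nlr.y_pooled)),
    )
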