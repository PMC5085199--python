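"""Study-level effect sizes on the analysis (log) scale.

Two measures are supported: the log ratio of means (log RoM) with its
delta-method variance, and the log odds ratio from a 2x2 table.  All
pooling downstream operates on these :class:`Estimate` objects; the
back-transform to the reporting scale (ratio, odds ratio, proportion)
happens only at the reporting boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .study_io import CategoryCountRow, StudyRecord

__all__ = ["Estimate", "log_rom", "log_or", "categories_to_or"]

MEASURES = ("log_rom", "log_or", "logit_sens", "logit_spec")


@dataclass(frozen=True)
class Estimate:
    """An effect on its analysis scale with its sampling variance."""

    study_id: str
    y: float
    v: float
    measure: str = "log_rom"

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        if not (self.v > 0 and math.isfinite(self.v)):
            raise ValueError(f"{self.study_id}: variance must be positive, got {self.v}")
        if not math.isfinite(self.y):
            raise ValueError(f"{self.study_id}: effect must be finite")

    @property
    def se(self) -> float:
        return math.sqrt(self.v)


def log_rom(r: StudyRecord) -> Estimate:
    """Log ratio of means with delta-method variance.

    y = ln(mean_case / mean_control) and

        v = sd_case^2 / (n_case * mean_case^2)
          + sd_control^2 / (n_control * mean_control^2)

    i.e. the sum of the squared coefficients of variation of the two
    group means.  The measure is scale-free: rescaling all four moments
    by a common assay factor leaves y and v unchanged, which is why a
    ratio is used when TSH assays differ across studies.
    """
    y = math.log(r.mean_case / r.mean_control)
    v = (r.sd_case**2 / (r.n_case * r.mean_case**2)
         + r.sd_control**2 / (r.n_control * r.mean_control**2))
    return Estimate(study_id=r.study_id, y=y, v=v, measure="log_rom")


def log_or(a: float, b: float, c: float, d: float,
           correction: float = 0.5, study_id: str = "") -> Estimate:
    """Log odds ratio from a 2x2 table.

    Layout: ``a`` cases exposed (high TSH), ``b`` controls exposed,
    ``c`` cases referent, ``d`` controls referent.  y = ln(ad/bc),
    v = 1/a + 1/b + 1/c + 1/d.  ``correction`` is added to every cell
    only when some cell is zero.

    Raises
    ------
    ValueError
        If a margin is empty, or if after correction a column still
        contains a zero (correction = 0 with a zero cell).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    if a + c < 1 or b + d < 1:
        raise ValueError("each group (cases, controls) needs at least one subject")
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + correction for x in (a, b, c, d))
    if (a == 0 and c == 0) or (b == 0 and d == 0) or min(a, b, c, d) == 0:
        raise ValueError("zero cell remains after correction; odds ratio undefined")
    y = math.log((a * d) / (b * c))
    v = 1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d
    return Estimate(study_id=study_id, y=y, v=v, measure="log_or")


def categories_to_or(row: CategoryCountRow,
                     exposed_range: tuple[float, float],
                     referent_range: tuple[float, float]) -> tuple[int, int, int, int]:
    """Collapse TSH category counts into a 2x2 exposure table.

    Both ranges are half-open ``[low, high)`` and must align exactly
    with the study's bin edges (a range cannot split a bin).  Returns
    ``(a, b, c, d)`` = (cases exposed, controls exposed, cases referent,
    controls referent) ready for :func:`log_or`.
    """
    a, c_ = _sum_range(row, exposed_range, "exposed")
    c, d = _sum_range(row, referent_range, "referent")
    return a, c_, c, d


def _sum_range(row: CategoryCountRow, rng: tuple[float, float], name: str) -> tuple[int, int]:
    lo, hi = rng
    edges = row.bin_edges
    if lo not in edges:
        raise ValueError(f"{row.study_id}: {name} range edge {lo} not among bin edges {edges}")
    if hi not in edges and not (math.isinf(hi) and math.isinf(edges[-1])):
        raise ValueError(f"{row.study_id}: {name} range edge {hi} not among bin edges {edges}")
    i = edges.index(lo)
    j = len(edges) - 1 if math.isinf(hi) else edges.index(hi)
    if j <= i:
        raise ValueError(f"{row.study_id}: empty {name} range [{lo}, {hi})")
    cases = sum(row.case_counts[i:j])
    controls = sum(row.control_counts[i:j])
    return cases, controls
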