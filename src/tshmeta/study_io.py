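"""Study-level data model and delimited-table IO.

The atom of the ratio-of-means arm is a :class:`StudyRecord`: one
case/control comparison of serum TSH (mU/L) with its stratification
labels.  Tables arrive as UTF-8 delimited text (comma by default, tab
accepted) with a header row.  Studies that report only a median and
range are converted to mean/SD with :func:`hozo_convert`.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "StudyRecord",
    "MedianRangeSummary",
    "CategoryCountRow",
    "StudyTableError",
    "hozo_convert",
    "read_study_table",
    "write_study_table",
    "size_class_from_n",
]

ETHNICITY_LEVELS = ("asian", "caucasian", "other")
AGE_LEVELS = ("adult", "children")
DESIGN_LEVELS = ("retrospective_cross_sectional", "other")
SIZE_LEVELS = ("small", "moderate", "large")
TUMOUR_SIZE_LEVELS = ("lt1cm", "ge1cm")
TNM_LEVELS = ("I_II", "III_IV")
NODE_LEVELS = ("yes", "no")
HISTOLOGY_LEVELS = ("PTC", "FTC", "other")

MISSING = "missing"


class StudyTableError(ValueError):
    """Raised when a study table fails validation.

    Collects every row-level problem so the caller sees all defects in
    one pass, not just the first.
    """

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("study table validation failed:\n" + "\n".join(self.problems))


def size_class_from_n(n_case: int) -> str:
    """Sample-size class from the number of cases.

    Bands: small < 200 cases, moderate 200-500, large > 500.
    """
    if n_case < 200:
        return "small"
    if n_case <= 500:
        return "moderate"
    return "large"


@dataclass
class StudyRecord:
    """One study's case/control TSH summary plus stratification labels.

    Means and SDs are in mU/L and must be strictly positive: TSH is a
    positive quantity and the ratio-of-means measure requires positive
    means.  ``size_class`` is always derived from ``n_case``.
    """

    study_id: str
    label: str
    n_case: int
    n_control: int
    mean_case: float
    sd_case: float
    mean_control: float
    sd_control: float
    ethnicity: str = MISSING
    age_group: str = MISSING
    design: str = MISSING
    quality_score: int | None = None
    tumour_size_class: str = MISSING
    tnm_stage: str = MISSING
    node_metastasis: str = MISSING
    histology: str = MISSING
    size_class: str = field(init=False)

    def __post_init__(self) -> None:
        if not self.study_id:
            raise ValueError("study_id must be non-empty")
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError(f"{self.study_id}: sample sizes must be >= 1")
        for name in ("mean_case", "sd_case", "mean_control", "sd_control"):
            val = getattr(self, name)
            if not math.isfinite(val) or val <= 0:
                raise ValueError(f"{self.study_id}: {name} must be strictly positive, got {val}")
        if self.quality_score is not None and not 0 <= self.quality_score <= 9:
            raise ValueError(f"{self.study_id}: quality_score must be in 0..9")
        self.ethnicity = _norm_level(self.ethnicity, ETHNICITY_LEVELS, "ethnicity", self.study_id)
        self.age_group = _norm_level(self.age_group, AGE_LEVELS, "age_group", self.study_id)
        self.design = _norm_level(self.design, DESIGN_LEVELS, "design", self.study_id)
        self.tumour_size_class = _norm_level(
            self.tumour_size_class, TUMOUR_SIZE_LEVELS, "tumour_size_class", self.study_id
        )
        self.tnm_stage = _norm_level(self.tnm_stage, TNM_LEVELS, "tnm_stage", self.study_id)
        self.node_metastasis = _norm_level(
            self.node_metastasis, NODE_LEVELS, "node_metastasis", self.study_id
        )
        self.histology = _norm_level(self.histology, HISTOLOGY_LEVELS, "histology", self.study_id)
        self.size_class = size_class_from_n(self.n_case)


def _norm_level(value: str | None, levels: Sequence[str], name: str, sid: str) -> str:
    """Case-insensitive normalisation of a categorical value; blank -> missing."""
    if value is None:
        return MISSING
    v = str(value).strip()
    if v == "" or v.lower() in ("missing", "na", "nan", "none"):
        return MISSING
    for lev in levels:
        if v.lower() == lev.lower():
            return lev
    raise ValueError(f"{sid}: {name} value {value!r} not in {levels}")


@dataclass(frozen=True)
class MedianRangeSummary:
    """A median with its full observed range, as some studies report TSH."""

    median: float
    minimum: float
    maximum: float
    n: int

    def __post_init__(self) -> None:
        if not (self.minimum <= self.median <= self.maximum):
            raise ValueError("require minimum <= median <= maximum")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def hozo_convert(s: MedianRangeSummary) -> tuple[float, float]:
    """Estimate mean and SD from a median and range.

    With a = minimum, m = median, b = maximum:

        mean = (a + 2m + b) / 4

    and the SD rule depends on sample size:

        n <= 15      sd = sqrt(((a - 2m + b)^2 / 4 + (b - a)^2) / 12)
        15 < n <= 70 sd = (b - a) / 4
        n > 70       sd = (b - a) / 6

    Band boundaries are closed on the left band (n = 15 uses the
    small-sample formula, n = 70 the quarter-range rule).

    Raises
    ------
    ValueError
        If the range is degenerate (maximum == minimum), which would
        produce sd = 0.
    """
    a, m, b, n = s.minimum, s.median, s.maximum, s.n
    if b == a:
        raise ValueError("degenerate range (maximum == minimum): sd would be 0")
    mean = (a + 2.0 * m + b) / 4.0
    if n <= 15:
        sd = math.sqrt(((a - 2.0 * m + b) ** 2 / 4.0 + (b - a) ** 2) / 12.0)
    elif n <= 70:
        sd = (b - a) / 4.0
    else:
        sd = (b - a) / 6.0
    return mean, sd


@dataclass
class CategoryCountRow:
    """Per-study case/control counts across ordered TSH bins.

    ``bin_edges`` has one more entry than each count list; the last edge
    may be ``inf``.  Bins are half-open ``[low, high)``.
    """

    study_id: str
    bin_edges: list[float]
    case_counts: list[int]
    control_counts: list[int]

    def __post_init__(self) -> None:
        edges = [float(e) for e in self.bin_edges]
        if len(edges) < 2:
            raise ValueError(f"{self.study_id}: need at least 2 bin edges")
        if any(hi <= lo for lo, hi in zip(edges, edges[1:])):
            raise ValueError(f"{self.study_id}: bin edges must be strictly increasing")
        if len(self.case_counts) != len(edges) - 1 or len(self.control_counts) != len(edges) - 1:
            raise ValueError(f"{self.study_id}: counts must have one entry per bin")
        if any(c < 0 for c in self.case_counts) or any(c < 0 for c in self.control_counts):
            raise ValueError(f"{self.study_id}: counts must be non-negative")
        self.bin_edges = edges

    @property
    def n_case(self) -> int:
        return int(sum(self.case_counts))

    @property
    def n_control(self) -> int:
        return int(sum(self.control_counts))


# ---------------------------------------------------------------------------
# Table reading

_ROM_REQUIRED = [
    "study_id", "label", "n_case", "n_control",
]
_ROM_MEAN_COLS = ["mean_case", "sd_case", "mean_control", "sd_control"]
_ROM_MEDIAN_COLS = [
    "median_case", "min_case", "max_case",
    "median_control", "min_control", "max_control",
]
_ROM_OPTIONAL = [
    "ethnicity", "age_group", "design", "quality_score",
    "tumour_size_class", "tnm_stage", "node_metastasis", "histology",
    "size_class",
]
_CAT_REQUIRED = ["study_id", "bin_low", "bin_high", "case_count", "control_count"]
_DIAG_REQUIRED = ["study_id", "cutoff_group", "tp", "fp", "fn", "tn"]


def _sniff_reader(path: Path):
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    delim = "\t" if ("\t" in lines[0] and "," not in lines[0]) else ","
    return csv.DictReader(lines, delimiter=delim)


def read_study_table(path: str | Path, schema: str = "rom") -> list:
    """Read and validate a delimited study table.

    Parameters
    ----------
    path
        CSV/TSV file with a header row; ``#`` lines are comments.
    schema
        ``"rom"`` -> list of :class:`StudyRecord` (median/min/max columns
        are converted through :func:`hozo_convert` for rows lacking a
        mean); ``"categories"`` -> list of :class:`CategoryCountRow`;
        ``"diagnostic"`` -> list of diagnostic 2x2 studies.

    Raises
    ------
    StudyTableError
        Naming every missing column or offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if schema == "rom":
        return _read_rom(path)
    if schema == "categories":
        return _read_categories(path)
    if schema == "diagnostic":
        return _read_diagnostic(path)
    raise ValueError(f"unknown schema {schema!r} (expected rom|categories|diagnostic)")


def _require_columns(fieldnames: Iterable[str], required: Sequence[str]) -> None:
    have = set(fieldnames or [])
    missing = [c for c in required if c not in have]
    if missing:
        raise StudyTableError([f"missing required column(s): {', '.join(missing)}"])


def _read_rom(path: Path) -> list[StudyRecord]:
    reader = _sniff_reader(path)
    _require_columns(reader.fieldnames, _ROM_REQUIRED)
    have = set(reader.fieldnames or [])
    has_means = all(c in have for c in _ROM_MEAN_COLS)
    has_medians = all(c in have for c in _ROM_MEDIAN_COLS)
    if not has_means and not has_medians:
        raise StudyTableError(
            ["need either mean/sd columns (" + ", ".join(_ROM_MEAN_COLS) + ") "
             "or median/range columns (" + ", ".join(_ROM_MEDIAN_COLS) + ")"]
        )

    records: list[StudyRecord] = []
    problems: list[str] = []
    seen: set[str] = set()
    for i, row in enumerate(reader, start=2):  # row 1 is the header
        sid = (row.get("study_id") or "").strip()
        try:
            if not sid:
                raise ValueError("empty study_id")
            if sid in seen:
                raise ValueError(f"duplicate study_id {sid!r}")
            n_case = _parse_int(row, "n_case")
            n_control = _parse_int(row, "n_control")
            if has_means and _present(row, "mean_case"):
                mc, sc = _parse_float(row, "mean_case"), _parse_float(row, "sd_case")
                mk, sk = _parse_float(row, "mean_control"), _parse_float(row, "sd_control")
            else:
                mc, sc = hozo_convert(MedianRangeSummary(
                    _parse_float(row, "median_case"), _parse_float(row, "min_case"),
                    _parse_float(row, "max_case"), n_case))
                mk, sk = hozo_convert(MedianRangeSummary(
                    _parse_float(row, "median_control"), _parse_float(row, "min_control"),
                    _parse_float(row, "max_control"), n_control))
            qs = row.get("quality_score")
            rec = StudyRecord(
                study_id=sid,
                label=(row.get("label") or sid).strip(),
                n_case=n_case, n_control=n_control,
                mean_case=mc, sd_case=sc, mean_control=mk, sd_control=sk,
                ethnicity=row.get("ethnicity", MISSING),
                age_group=row.get("age_group", MISSING),
                design=row.get("design", MISSING),
                quality_score=int(qs) if qs not in (None, "", "NA") else None,
                tumour_size_class=row.get("tumour_size_class", MISSING),
                tnm_stage=row.get("tnm_stage", MISSING),
                node_metastasis=row.get("node_metastasis", MISSING),
                histology=row.get("histology", MISSING),
            )
            supplied = (row.get("size_class") or "").strip().lower()
            if supplied and supplied != rec.size_class:
                warnings.warn(
                    f"row {i} ({sid}): supplied size_class {supplied!r} disagrees with "
                    f"the n_case-derived class {rec.size_class!r}; using the derived class",
                    stacklevel=2,
                )
            seen.add(sid)
            records.append(rec)
        except (ValueError, KeyError) as exc:
            problems.append(f"row {i}: {exc}")
    if problems:
        raise StudyTableError(problems)
    return records


def _read_categories(path: Path) -> list[CategoryCountRow]:
    reader = _sniff_reader(path)
    _require_columns(reader.fieldnames, _CAT_REQUIRED)
    per_study: dict[str, list[tuple[float, float, int, int]]] = {}
    problems: list[str] = []
    for i, row in enumerate(reader, start=2):
        sid = (row.get("study_id") or "").strip()
        try:
            lo = _parse_float(row, "bin_low", allow_zero=True)
            hi = float(row["bin_high"]) if row["bin_high"].strip().lower() in ("inf", "+inf") \
                else _parse_float(row, "bin_high")
            per_study.setdefault(sid, []).append(
                (lo, hi, _parse_int(row, "case_count", minimum=0),
                 _parse_int(row, "control_count", minimum=0)))
        except (ValueError, KeyError) as exc:
            problems.append(f"row {i}: {exc}")
    rows: list[CategoryCountRow] = []
    for sid, bins in per_study.items():
        bins.sort(key=lambda t: t[0])
        edges = [b[0] for b in bins] + [bins[-1][1]]
        try:
            for (lo1, hi1, *_), (lo2, *_rest) in zip(bins, bins[1:]):
                if hi1 != lo2:
                    raise ValueError(f"bins not contiguous at edge {hi1} vs {lo2}")
            rows.append(CategoryCountRow(
                study_id=sid, bin_edges=edges,
                case_counts=[b[2] for b in bins],
                control_counts=[b[3] for b in bins]))
        except ValueError as exc:
            problems.append(f"study {sid}: {exc}")
    if problems:
        raise StudyTableError(problems)
    return rows


def _read_diagnostic(path: Path):
    from .diagnostic_meta import DiagnosticStudy  # local import to avoid a cycle

    reader = _sniff_reader(path)
    _require_columns(reader.fieldnames, _DIAG_REQUIRED)
    studies = []
    problems: list[str] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(reader, start=2):
        sid = (row.get("study_id") or "").strip()
        try:
            key = (sid, row["cutoff_group"].strip())
            if key in seen:
                raise ValueError(f"duplicate study_id/cutoff_group {key}")
            studies.append(DiagnosticStudy(
                study_id=sid, cutoff_group=row["cutoff_group"].strip(),
                tp=_parse_int(row, "tp", minimum=0), fp=_parse_int(row, "fp", minimum=0),
                fn=_parse_int(row, "fn", minimum=0), tn=_parse_int(row, "tn", minimum=0)))
            seen.add(key)
        except (ValueError, KeyError) as exc:
            problems.append(f"row {i}: {exc}")
    if problems:
        raise StudyTableError(problems)
    return studies


def _present(row: dict, col: str) -> bool:
    v = row.get(col)
    return v is not None and str(v).strip() != ""


def _parse_float(row: dict, col: str, allow_zero: bool = False) -> float:
    raw = row.get(col)
    if raw is None or str(raw).strip() == "":
        raise ValueError(f"{col} is empty")
    try:
        val = float(raw)
    except ValueError:
        raise ValueError(f"{col} is not numeric: {raw!r}") from None
    if not math.isfinite(val) or val < 0 or (val == 0 and not allow_zero):
        raise ValueError(f"{col} must be {'non-negative' if allow_zero else 'positive'}, got {raw}")
    return val


def _parse_int(row: dict, col: str, minimum: int = 1) -> int:
    raw = row.get(col)
    if raw is None or str(raw).strip() == "":
        raise ValueError(f"{col} is empty")
    try:
        val = int(float(raw))
    except ValueError:
        raise ValueError(f"{col} is not numeric: {raw!r}") from None
    if float(raw) != val:
        raise ValueError(f"{col} must be an integer, got {raw}")
    if val < minimum:
        raise ValueError(f"{col} must be >= {minimum}, got {val}")
    return val


_WRITE_COLS = [
    "study_id", "label", "n_case", "n_control",
    "mean_case", "sd_case", "mean_control", "sd_control",
    "ethnicity", "age_group", "design", "quality_score",
    "tumour_size_class", "tnm_stage", "node_metastasis", "histology",
]


def write_study_table(records: Sequence[StudyRecord], path: str | Path,
                      header_comment: str | None = None) -> None:
    """Write records as CSV in the dialect :func:`read_study_table` reads."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        writer = csv.writer(fh)
        writer.writerow(_WRITE_COLS)
        for r in records:
            writer.writerow([
                r.study_id, r.label, r.n_case, r.n_control,
                repr(r.mean_case), repr(r.sd_case), repr(r.mean_control), repr(r.sd_control),
                r.ethnicity, r.age_group, r.design,
                "" if r.quality_score is None else r.quality_score,
                r.tumour_size_class, r.tnm_stage, r.node_metastasis, r.histology,
            ])
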