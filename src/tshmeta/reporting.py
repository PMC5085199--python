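"""Table-shaped reports and the end-to-end analysis pipeline.

Every number that reaches a TSV table also lives, at full precision, in
a single machine-readable JSON report: the TSVs round to two decimals
for reading, the JSON is the source of truth.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .bias_heterogeneity import begg_test, egger_test, funnel_data, galbraith_data
from .diagnostic_meta import DiagnosticStudy, lr_classify, plr_nlr, sens_spec, sroc_moses
from .effect_measures import Estimate, log_rom
from .meta_regression import screen_modifiers
from .pooling import PooledResult, compare_two_pooled, leave_one_out, pool_dl, pool_fixed, subgroup_pool
from .study_io import StudyRecord, read_study_table

__all__ = ["AnalysisConfig", "run_pipeline", "pooled_row", "to_jsonable"]

# factors whose two levels are contrasted pairwise in the report
_CONTRAST_FACTORS = {
    "tumour_size_class": ("ge1cm", "lt1cm"),
    "tnm_stage": ("III_IV", "I_II"),
    "node_metastasis": ("yes", "no"),
}
_DEFAULT_SUBGROUPS = ("ethnicity", "age_group", "size_class", "design")
_DEFAULT_COVARIATES = ("ethnicity", "size_class", "design", "quality_score")


@dataclass
class AnalysisConfig:
    """Everything one pipeline run needs; see the CLI for the flag surface."""

    studies_path: str | Path | None = None
    diagnostic_path: str | Path | None = None
    model: str = "random"
    subgroup_factors: Sequence[str] = _DEFAULT_SUBGROUPS
    covariates: Sequence[str] = _DEFAULT_COVARIATES
    alpha: float = 0.05
    seed: int = 0
    outdir: str | Path = "tshmeta_out"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def to_jsonable(obj):
    """Recursively convert dataclasses/containers to JSON-ready values."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: to_jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, float):
        return None if math.isnan(obj) else obj
    if isinstance(obj, Path):
        return str(obj)
    return obj


def pooled_row(label: str, res: PooledResult,
               n_case: int | None = None, n_control: int | None = None) -> dict:
    """One report-table row: subgroup, k, n, effect (CI), P(Z), P(Q), I2%."""
    row = {
        "subgroup": label,
        "k": res.k,
        "effect": res.effect,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "p_z": res.p_z,
        "p_q": res.p_q,
        "i_squared_pct": 100.0 * res.i_squared,
        "tau_squared": res.tau_squared,
    }
    if n_case is not None:
        row["n_case"], row["n_control"] = n_case, n_control
    return row


def _format_table(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    for col in df.columns:
        if df[col].dtype.kind == "f":
            df[col] = df[col].round(2)
    return df


def _subgroup_sizes(records: Sequence[StudyRecord], factor: str) -> dict[str, tuple[int, int]]:
    sizes: dict[str, list[int]] = {}
    for r in records:
        level = getattr(r, factor)
        level = "unknown" if level in (None, "missing") else str(level)
        nc, nn = sizes.setdefault(level, [0, 0])
        sizes[level] = [nc + r.n_case, nn + r.n_control]
    return {k: (v[0], v[1]) for k, v in sizes.items()}


def run_pipeline(cfg: AnalysisConfig) -> dict:
    """Run every applicable stage and write the report bundle.

    Returns the in-memory report dict (the same object serialized to
    ``report.json``).  Stages that need inputs the config does not
    provide are skipped; stage errors are re-raised annotated with the
    stage name.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # outdir is excluded so reruns into different directories stay byte-identical
    config = {k: v for k, v in to_jsonable(cfg).items() if k != "outdir"}
    report: dict = {"config": config}

    if cfg.studies_path is not None:
        records = _stage("read_studies", read_study_table, cfg.studies_path, "rom")
        estimates = [log_rom(r) for r in records]
        report["rom"] = _rom_stages(records, estimates, cfg, outdir)

    if cfg.diagnostic_path is not None:
        studies = _stage("read_diagnostic", read_study_table, cfg.diagnostic_path, "diagnostic")
        report["diagnostic"] = _diagnostic_stages(studies, cfg, outdir)

    (outdir / "report.json").write_text(
        json.dumps(to_jsonable(report), indent=1, sort_keys=True), encoding="utf-8")
    _write_run_log(outdir, cfg)
    return report


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc


def _rom_stages(records: list[StudyRecord], estimates: list[Estimate],
                cfg: AnalysisConfig, outdir: Path) -> dict:
    rom: dict = {}
    pool = pool_dl if cfg.model == "random" else pool_fixed
    overall = _stage("pool_overall", pool, estimates, alpha=cfg.alpha)
    rom["overall"] = overall
    rows = [pooled_row("all", overall,
                       sum(r.n_case for r in records), sum(r.n_control for r in records))]

    rom["subgroups"] = {}
    for factor in cfg.subgroup_factors:
        levels = _stage(f"subgroup[{factor}]", subgroup_pool, records, factor, alpha=cfg.alpha)
        rom["subgroups"][factor] = levels
        sizes = _subgroup_sizes(records, factor)
        for level, res in levels.items():
            rows.append(pooled_row(f"{factor}={level}", res, *sizes[level]))
    _format_table(rows).to_csv(outdir / "pooled.tsv", sep="\t", index=False)

    contrasts = {}
    for factor, (lev_a, lev_b) in _CONTRAST_FACTORS.items():
        present = {getattr(r, factor) for r in records}
        if lev_a in present and lev_b in present:
            groups = subgroup_pool(records, factor, alpha=cfg.alpha)
            z, p = compare_two_pooled(groups[lev_a], groups[lev_b])
            contrasts[factor] = {"levels": (lev_a, lev_b), "z": z, "p": p,
                                 "pooled": {lev_a: groups[lev_a], lev_b: groups[lev_b]}}
    rom["contrasts"] = contrasts

    if len(estimates) >= 3:
        covs = _covariate_table(records, cfg.covariates)
        if covs.shape[1]:
            rom["meta_regression"] = _stage("meta_regression", screen_modifiers,
                                            estimates, covs)
        rom["leave_one_out"] = _stage("leave_one_out", leave_one_out,
                                      estimates, alpha=cfg.alpha)
        loo_rows = [pooled_row(f"omit {sid}", res) for sid, res in rom["leave_one_out"]]
        _format_table(loo_rows).to_csv(outdir / "leave_one_out.tsv", sep="\t", index=False)
        rom["egger"] = _stage("egger", egger_test, estimates)
        rom["begg"] = _stage("begg", begg_test, estimates)
        funnel = _stage("funnel", funnel_data, estimates, overall)
        rom["funnel"] = funnel
        pd.DataFrame(funnel["points"], columns=["study_id", "y", "se"]).to_csv(
            outdir / "funnel.tsv", sep="\t", index=False)
        gal = _stage("galbraith", galbraith_data, estimates)
        rom["galbraith"] = gal
        pd.DataFrame([dataclasses.asdict(g) for g in gal]).to_csv(
            outdir / "galbraith.tsv", sep="\t", index=False)
    return rom


def _covariate_table(records: Sequence[StudyRecord], names: Sequence[str]) -> pd.DataFrame:
    data = {}
    for name in names:
        col = [getattr(r, name) for r in records]
        # drop covariates that are entirely missing or constant
        vals = [c for c in col if c not in (None, "missing")]
        if len(set(vals)) < 2 or len(vals) < len(col):
            continue
        data[name] = col
    return pd.DataFrame(data, index=[r.study_id for r in records])


def _diagnostic_stages(studies: list[DiagnosticStudy], cfg: AnalysisConfig,
                       outdir: Path) -> dict:
    diag: dict = {"groups": {}}
    table_rows = []
    matrix_rows = []
    by_group: dict[str, list[DiagnosticStudy]] = {}
    for s in studies:
        by_group.setdefault(s.cutoff_group, []).append(s)
    for group, members in sorted(by_group.items()):
        for s in members:
            sens, spec, *_ = sens_spec(s)
            plr, nlr = plr_nlr(min(max(sens, 1e-9), 1 - 1e-9),
                               min(max(spec, 1e-9), 1 - 1e-9))
            matrix_rows.append({"study_id": s.study_id, "cutoff_group": group,
                                "sens": sens, "spec": spec, "plr": plr, "nlr": nlr,
                                "quadrant": lr_classify(plr, nlr)})
        if len(members) < 3:
            diag["groups"][group] = {"k": len(members),
                                     "note": "fewer than 3 studies; SROC not fitted"}
            continue
        summary = _stage(f"sroc[{group}]", sroc_moses, members, seed=cfg.seed,
                         alpha=cfg.alpha)
        diag["groups"][group] = summary
        table_rows.append({
            "cutoff_group": group, "k": summary.k,
            "spec": summary.pooled_spec.effect,
            "spec_ci_low": summary.pooled_spec.ci_low,
            "spec_ci_high": summary.pooled_spec.ci_high,
            "sens": summary.pooled_sens.effect,
            "sens_ci_low": summary.pooled_sens.ci_low,
            "sens_ci_high": summary.pooled_sens.ci_high,
            "ausroc": summary.ausroc,
            "ausroc_ci_low": summary.ausroc_ci[0] if summary.ausroc_ci else float("nan"),
            "ausroc_ci_high": summary.ausroc_ci[1] if summary.ausroc_ci else float("nan"),
            "utility": summary.utility,
        })
    if table_rows:
        _format_table(table_rows).to_csv(outdir / "sroc.tsv", sep="\t", index=False)
    if matrix_rows:
        _format_table(matrix_rows).to_csv(outdir / "likelihood_matrix.tsv",
                                          sep="\t", index=False)
    return diag


def _write_run_log(outdir: Path, cfg: AnalysisConfig) -> None:
    import numpy, pandas, scipy

    lines = [
        f"tshmeta {__version__}",
        f"numpy {numpy.__version__}, scipy {scipy.__version__}, pandas {pandas.__version__}",
        f"seed {cfg.seed}",
        f"config {json.dumps(to_jsonable(cfg), sort_keys=True)}",
    ]
    (outdir / "run.log").write_text("\n".join(lines) + "\n", encoding="utf-8")
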