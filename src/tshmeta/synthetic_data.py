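"""Synthetic study-level data with known truth.

Emulates the generative structure the meta-analysis assumes: each
study's true log ratio of case/control mean TSH is mu + tau * u_i
(between-study normal heterogeneity), within-study TSH values are
lognormal (positive and right-skewed, like serum TSH), and the
observed means/SDs are the *sample* statistics of the drawn values, so
delta-method variances are exercised against genuine sampling noise.
Category counts and diagnostic 2x2 tables are tabulated from the same
latent distributions, keeping the ratio-of-means, odds-ratio and
diagnostic arms internally consistent.

Defaults mirror a literature-scale synthesis of serum TSH in thyroid
cancer: 56 studies, true ratio of means 1.44, substantial between-study
heterogeneity, case series from a few dozen to several hundred, and a
predominantly Asian study mix.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .study_io import CategoryCountRow, StudyRecord, write_study_table
from .diagnostic_meta import DiagnosticStudy

__all__ = [
    "RomSimConfig",
    "DiagSimConfig",
    "RomTruth",
    "DiagTruth",
    "simulate_rom_studies",
    "simulate_diagnostic_studies",
    "write_rom_bundle",
]

_ETHNICITY_PROBS = {"asian": 0.75, "caucasian": 0.2, "other": 0.05}
_AGE_PROBS = {"adult": 0.95, "children": 0.05}
_DESIGN_PROBS = {"retrospective_cross_sectional": 0.85, "other": 0.15}


@dataclass
class RomSimConfig:
    """Configuration of the ratio-of-means study generator.

    ``true_log_rom`` is the mean of the study-level true log ratios;
    ``tau`` their between-study SD.  Study-level control mean TSH is
    drawn lognormally (location/scale on the log scale, mU/L) and the
    within-study coefficient of variation controls the spread of
    individual TSH values.  ``small_study_effect`` adds
    ``lambda * se_i`` to each study's true log ratio, the classic
    small-study bias; zero means none.
    """

    k: int = 56
    true_log_rom: float = math.log(1.44)
    tau: float = 0.3
    control_mean_log_location: float = math.log(1.5)
    control_mean_log_scale: float = 0.3
    cv_case: float = 0.9
    cv_control: float = 0.9
    n_case_range: tuple[int, int] = (20, 800)
    n_control_range: tuple[int, int] = (40, 2000)
    small_study_effect: float = 0.0
    bin_edges: tuple[float, ...] | None = None
    distribution: str = "lognormal"  # or "gamma"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.cv_case <= 0 or self.cv_control <= 0:
            raise ValueError("coefficients of variation must be > 0")
        for name in ("n_case_range", "n_control_range"):
            lo, hi = getattr(self, name)
            if lo < 2 or hi < lo:
                raise ValueError(f"{name} must be a non-empty range with lo >= 2")
        if self.distribution not in ("lognormal", "gamma"):
            raise ValueError("distribution must be 'lognormal' or 'gamma'")
        if self.bin_edges is not None:
            edges = tuple(float(e) for e in self.bin_edges)
            if any(b <= a for a, b in zip(edges, edges[1:])):
                raise ValueError("bin_edges must be strictly increasing")
            self.bin_edges = edges


@dataclass
class RomTruth:
    """What the generator knows: the target of every recovery check."""

    true_log_rom: float
    tau: float
    theta: list[float]
    seed: int


def _draw_positive(rng: np.random.Generator, mean: float, cv: float,
                   n: int, distribution: str) -> np.ndarray:
    """Draw n positive values with the given mean and coefficient of variation."""
    if distribution == "lognormal":
        sigma2 = math.log(1.0 + cv * cv)
        mu = math.log(mean) - sigma2 / 2.0
        return rng.lognormal(mu, math.sqrt(sigma2), size=n)
    shape = 1.0 / (cv * cv)
    return rng.gamma(shape, mean / shape, size=n)


def simulate_rom_studies(cfg: RomSimConfig
                         ) -> tuple[list[StudyRecord], list[CategoryCountRow] | None, RomTruth]:
    """Generate study records (and optional category counts) with known truth.

    Per study i: theta_i = true_log_rom + tau * u_i; control values are
    drawn from the positive within-study distribution at the study's
    control mean; case values at control_mean * exp(theta_i).  Observed
    means/SDs are sample statistics.  When ``bin_edges`` is set, the
    same drawn values are tabulated into half-open bins [low, high)
    with an implicit trailing bin up to infinity, guaranteeing the
    category counts and the mean/SD summaries describe the same data.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[StudyRecord] = []
    cat_rows: list[CategoryCountRow] | None = [] if cfg.bin_edges is not None else None
    thetas: list[float] = []

    eth_levels, eth_p = zip(*_ETHNICITY_PROBS.items())
    age_levels, age_p = zip(*_AGE_PROBS.items())
    des_levels, des_p = zip(*_DESIGN_PROBS.items())

    for i in range(cfg.k):
        sid = f"S{i + 1:03d}"
        n_case = int(rng.integers(cfg.n_case_range[0], cfg.n_case_range[1] + 1))
        n_control = int(rng.integers(cfg.n_control_range[0], cfg.n_control_range[1] + 1))
        theta = cfg.true_log_rom + cfg.tau * rng.standard_normal()
        if cfg.small_study_effect != 0.0:
            # anticipated standard error of the study's log ratio
            se_i = math.sqrt(cfg.cv_case**2 / n_case + cfg.cv_control**2 / n_control)
            theta += cfg.small_study_effect * se_i
        control_mean = float(rng.lognormal(cfg.control_mean_log_location,
                                           cfg.control_mean_log_scale))
        case_mean = control_mean * math.exp(theta)

        control_vals = _draw_positive(rng, control_mean, cfg.cv_control, n_control,
                                      cfg.distribution)
        case_vals = _draw_positive(rng, case_mean, cfg.cv_case, n_case, cfg.distribution)

        rec = StudyRecord(
            study_id=sid, label=f"Synthetic {i + 1}",
            n_case=n_case, n_control=n_control,
            mean_case=float(case_vals.mean()), sd_case=float(case_vals.std(ddof=1)),
            mean_control=float(control_vals.mean()),
            sd_control=float(control_vals.std(ddof=1)),
            ethnicity=str(rng.choice(eth_levels, p=eth_p)),
            age_group=str(rng.choice(age_levels, p=age_p)),
            design=str(rng.choice(des_levels, p=des_p)),
            quality_score=int(rng.integers(5, 10)),
        )
        records.append(rec)
        thetas.append(theta)

        if cat_rows is not None:
            edges = list(cfg.bin_edges) + [math.inf]
            case_counts = np.histogram(case_vals, bins=edges)[0]
            ctrl_counts = np.histogram(control_vals, bins=edges)[0]
            cat_rows.append(CategoryCountRow(
                study_id=sid, bin_edges=edges,
                case_counts=[int(c) for c in case_counts],
                control_counts=[int(c) for c in ctrl_counts]))

    truth = RomTruth(true_log_rom=cfg.true_log_rom, tau=cfg.tau,
                     theta=thetas, seed=cfg.seed)
    return records, cat_rows, truth


@dataclass
class DiagSimConfig:
    """Configuration of the diagnostic 2x2 generator.

    Study-level (logit sens, logit spec) pairs are bivariate normal
    around the stated means; TP ~ Binomial(n_case, sens) and
    TN ~ Binomial(n_control, spec).  Defaults echo a mid-band TSH
    cut-off (sensitivity ~0.76, specificity ~0.44, 22 studies).
    """

    k: int = 22
    mean_logit_sens: float = math.log(0.76 / 0.24)
    mean_logit_spec: float = math.log(0.44 / 0.56)
    sd_logit_sens: float = 0.5
    sd_logit_spec: float = 0.5
    correlation: float = -0.3
    n_case_range: tuple[int, int] = (20, 800)
    n_control_range: tuple[int, int] = (40, 2000)
    cutoff_group: str = "0.5to1.5"
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.correlation <= 1.0:
            raise ValueError("correlation must lie in [-1, 1]")
        if self.sd_logit_sens < 0 or self.sd_logit_spec < 0:
            raise ValueError("logit SDs must be >= 0")


@dataclass
class DiagTruth:
    mean_logit_sens: float
    mean_logit_spec: float
    latent_logit_sens: list[float]
    latent_logit_spec: list[float]
    seed: int


def simulate_diagnostic_studies(cfg: DiagSimConfig
                                ) -> tuple[list[DiagnosticStudy], DiagTruth]:
    """Generate diagnostic 2x2 tables with known latent accuracy."""
    from scipy.special import expit

    rng = np.random.default_rng(cfg.seed)
    cov = np.array([
        [cfg.sd_logit_sens**2,
         cfg.correlation * cfg.sd_logit_sens * cfg.sd_logit_spec],
        [cfg.correlation * cfg.sd_logit_sens * cfg.sd_logit_spec,
         cfg.sd_logit_spec**2],
    ])
    mean = np.array([cfg.mean_logit_sens, cfg.mean_logit_spec])
    latent = rng.multivariate_normal(mean, cov, size=cfg.k)

    studies: list[DiagnosticStudy] = []
    for i, (ls, lp) in enumerate(latent):
        n_case = int(rng.integers(cfg.n_case_range[0], cfg.n_case_range[1] + 1))
        n_control = int(rng.integers(cfg.n_control_range[0], cfg.n_control_range[1] + 1))
        sens = float(expit(ls))
        spec = float(expit(lp))
        tp = int(rng.binomial(n_case, sens))
        tn = int(rng.binomial(n_control, spec))
        studies.append(DiagnosticStudy(
            study_id=f"D{i + 1:03d}", cutoff_group=cfg.cutoff_group,
            tp=tp, fn=n_case - tp, tn=tn, fp=n_control - tn))
    truth = DiagTruth(mean_logit_sens=cfg.mean_logit_sens,
                      mean_logit_spec=cfg.mean_logit_spec,
                      latent_logit_sens=[float(x) for x in latent[:, 0]],
                      latent_logit_spec=[float(x) for x in latent[:, 1]],
                      seed=cfg.seed)
    return studies, truth


def write_rom_bundle(cfg: RomSimConfig, outdir: str | Path) -> dict[str, Path]:
    """Simulate and write the CSV dialects study_io reads, plus truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, cats, truth = simulate_rom_studies(cfg)
    paths = {"studies": outdir / "studies.csv", "truth": outdir / "truth.json"}
    write_study_table(records, paths["studies"], header_comment=f"seed={cfg.seed}")
    if cats is not None:
        paths["categories"] = outdir / "categories.csv"
        with paths["categories"].open("w", encoding="utf-8") as fh:
            fh.write(f"# seed={cfg.seed}\n")
            fh.write("study_id,bin_low,bin_high,case_count,control_count\n")
            for row in cats:
                for lo, hi, cc, nc in zip(row.bin_edges, row.bin_edges[1:],
                                          row.case_counts, row.control_counts):
                    hi_s = "inf" if math.isinf(hi) else repr(hi)
                    fh.write(f"{row.study_id},{lo!r},{hi_s},{cc},{nc}\n")
    paths["truth"].write_text(json.dumps(asdict(truth), indent=1), encoding="utf-8")
    return paths
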