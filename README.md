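# tshmeta

Study-level meta-analysis of serum thyrotropin (TSH) between thyroid-cancer
cases and benign-nodule controls — and, more generally, of any strictly
positive biomarker compared between two groups across many studies.

Because TSH assays differ between laboratories, the package expresses each
study's effect as the **ratio of means** (RoM),

    RoM_i = x̄_case,i / x̄_control,i,    y_i = ln RoM_i,

analysed on the log scale with the delta-method variance

    v_i = s²_case,i / (n_case,i · x̄²_case,i) + s²_control,i / (n_control,i · x̄²_control,i),

so that assay-scale differences cancel. Study effects are combined with
DerSimonian–Laird random effects (τ² by the moment estimator, Cochran's Q,
I² = (Q − df)/Q), stratified by study-level factors, screened for effect
modifiers with REML meta-regression, and checked for small-study effects with
Egger's regression and Begg's rank-correlation tests plus funnel/Galbraith
coordinates. A categorical arm pools log odds ratios built from per-study TSH
bin counts, and a diagnostic arm pools sensitivity/specificity on the logit
scale, pools likelihood ratios, and fits the Moses–Littenberg summary ROC
(D = a + b·S with D = logit TPR − logit FPR, S = logit TPR + logit FPR) with
its area (AUSROC). A synthetic study-level generator with known truth makes
every stage testable without any external data.

Intended users: epidemiologists and biostatisticians running or auditing
biomarker meta-analyses, and anyone needing a transparent, fully tested
reference implementation of the RoM + SROC pipeline.

## Worked example

```python
from tshmeta import RomSimConfig, simulate_rom_studies, log_rom, pool_dl, egger_test

cfg = RomSimConfig(k=12, seed=42)          # 12 studies, true RoM 1.44, tau 0.3
records, _, truth = simulate_rom_studies(cfg)
ests = [log_rom(r) for r in records]
res = pool_dl(ests)
print(f"RoM {res.effect:.2f} (95% CI {res.ci_low:.2f}-{res.ci_high:.2f}), "
      f"P(Z) {res.p_z:.2g}, Q {res.Q:.1f} on {res.df} df, "
      f"I2 {100*res.i_squared:.1f}%, tau2 {res.tau_squared:.3f}")
eg = egger_test(ests)
print(f"Egger intercept {eg.intercept:.2f} (p = {eg.p:.2f})")
```

prints

```
RoM 1.45 (95% CI 1.19-1.76), P(Z) 0.00019, Q 255.6 on 11 df, I2 95.7%, tau2 0.111
Egger intercept -6.93 (p = 0.10)
```

The pooled ratio of means 1.45 says cases run ~45% higher mean TSH than
controls in this simulated literature (the generator's true ratio is 1.44);
the CI excludes 1 (P(Z) < 0.001). Q far above its 11 degrees of freedom and
I² ≈ 96% signal strong between-study heterogeneity — exactly what the
generator's τ = 0.3 injects — and τ² ≈ 0.11 ≈ 0.3² recovers it. The Egger
intercept is compatible with no small-study effect (p = 0.10), as expected
with none simulated.

The same pipeline runs from the shell:

```bash
tshmeta simulate --k 56 --seed 1 --diagnostic --out sim/
tshmeta all sim/studies.csv --diagnostic-table sim/diagnostic.csv --seed 1 --out report/
```

which writes `pooled.tsv` (overall + subgroup rows), `leave_one_out.tsv`,
`funnel.tsv`, `galbraith.tsv`, `sroc.tsv`, `likelihood_matrix.tsv` and a
full-precision `report.json` holding every number in every table.

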