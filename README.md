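# centrosurv

Analysis toolkit for studying the centrosome-clustering kinesin **KIFC1
(HSET)** as a prognostic marker in serous ovarian carcinoma. Cancer
cells with amplified centrosomes avoid lethal multipolar mitoses by
clustering their extra centrosomes, and KIFC1 is the motor that does
the clustering — which makes its expression a candidate readout of
tumor aggressiveness. `centrosurv` packages the full quantitative chain
used to test that idea:

* **IHC weighted-index scoring** — staining intensity (0–3) × percent
  positive cells, `WI ∈ [0, 300]`, pooled over microscope fields, with
  t-test / ANOVA + Tukey HSD group comparisons.
* **Survival machinery from first principles** — Kaplan–Meier
  product-limit curves, the two-group log-rank test, **maximally
  selected log-rank cut-points** (the marker threshold maximizing the
  log-rank χ², with both the naive p and a permutation-adjusted p that
  corrects its selection bias), and **Cox proportional-hazards**
  regression (Newton–Raphson on the partial likelihood, Efron/Breslow
  ties, monotone-likelihood detection).
* **Expression analytics** — a GEO Series Matrix reader, probe→gene
  collapsing, the KIFC1-anchored Pearson correlation panel over
  centrosome-amplification (CA) driver genes, and the cumulative
  **centrosome amplification index** (CAI: per-sample sum of log2
  expression over a centrosome gene panel).
* **GSEA** — signal-to-noise ranking, weighted KS running-sum
  enrichment scores, phenotype permutations, NES, and pooled FDR q
  (significance at FDR < 0.25 and nominal p < 0.05).
* **A synthetic-cohort simulator** — correlated log2 expression with a
  prescribed KIFC1-anchored correlation pattern, clinical covariates,
  and proportional-hazards survival with a true hazard ratio tied to
  KIFC1 — so the whole pipeline is testable with no external downloads.

The survival and GSEA cores follow scikit-learn estimator conventions
(`CoxPH`, `KaplanMeier`, `MaximallySelectedCutpoint`, `GSEA` with
`fit`/fitted attributes); module-level functions (`cox_fit`,
`km_estimate`, `optimal_cutpoint`, `gsea`, …) are thin wrappers.

## Worked example

```python
import centrosurv as cs

cfg = cs.SyntheticCohortConfig(n_samples=154, seed=42)   # study-sized cohort
cohort = cs.generate_cohort(cfg)                         # true HR = 2.14 per SD of KIFC1
res = cs.stratified_survival_analysis(cohort.expression, cohort.clinical)

print(res.n, res.cutpoint.threshold, res.cutpoint.chi2_max)
print(res.cox_univariate.summary().round(3))
```

prints

```
n = 154
threshold = 7.531  chi2 = 36.98  naive p = 1.196e-09
             coef     se    HR  HR_ci_lower  HR_ci_upper    p
KIFC1_high  1.466  0.261  4.33        2.595        7.225  0.0
```

The cohort was generated with a true hazard ratio of 2.14 **per SD of
KIFC1**, yet the dichotomized high/low fit reports HR ≈ 4.3: the
optimally selected threshold both changes the effect scale and inflates
it through selection. This is exactly the bias the
`MaximallySelectedCutpoint(n_permutations=...)` adjusted p-value
quantifies — under a true null the naive p rejects at ~45 % instead of
5 %, while the permutation-adjusted p stays calibrated. The correlation
panel on the same cohort recovers the prescribed anchored pattern
(CCNA2 and NEK2 at the top, r ≈ 0.62 and 0.60 at large n).

A shell workflow is available too:

```sh
centrosurv simulate --n 154 --seed 42 --hr 2.14 --out cohort/
centrosurv run --config pipeline.yaml        # ingest → survival → correlations → CAI → GSEA
centrosurv gsea --expression cohort/expression.csv --clinical cohort/clinical.csv \
    --gene-sets sets.gmt --split median --out gsea_out/
```

Every pipeline run writes a `manifest.json` (config hash, seed,
per-stage seeds) from which the run is bit-reproducible.

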