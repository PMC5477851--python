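# Methods

`centrosurv` implements the quantitative analysis chain used to link
expression of the centrosome-clustering kinesin KIFC1 (HSET) to tumor
grade, centrosome-amplification (CA) gene programs and overall survival
(OS) in serous ovarian carcinoma, together with a synthetic-cohort
simulator that emulates the assumed data-generating process so every
stage is testable without access to the original microarray deposit.

## IHC weighted-index scoring

Staining intensity per cell is scored on the ordinal scale 0 (none) to
3 (high). For a tissue scored over several microscope fields (by
default 10 fields of ~50 cells, ~500 cells in total), the percent of
positive cells is pooled over fields:

    percent_positive = 100 * (cells with intensity >= 1) / (all cells),

and the weighted index is

    WI = intensity_score * percent_positive,  WI in [0, 300].

Pooling (rather than averaging per-field percentages) makes the score
robust to unequal field sizes and invariant to how cells are split
across fields. The intensity score is in practice a single
pathologist-assigned call per tissue; when only raw counts are
available the package substitutes the modal intensity among positive
cells, breaking ties toward the higher intensity. This surrogate is
deterministic and conservative in the sense that two scorers of the
same counts always agree; it is not a model of inter-observer
variation. Group comparisons use a two-tailed t-test for two groups and
one-way ANOVA with Tukey's HSD for more, at the 0.05 level.

## Survival machinery

All survival estimators are written from first principles (the
installed `lifelines` package is used only as an independent
cross-check in the test suite).

* **Kaplan-Meier.** The product-limit estimator
  `S(t) = prod_{t_i <= t} (1 - d_i / n_i)` over distinct event times;
  observations censored exactly at an event time remain in that time's
  risk set (the standard convention).
* **Log-rank.** At each distinct event time the observed events in
  group 1 are compared with the hypergeometric expectation
  `d * n1/n`, with variance `d (n1/n)(1 - n1/n)(n - d)/(n - 1)`;
  `chi2 = (O1 - E1)^2 / V` on 1 df.
* **Maximally selected cut-point.** Candidate thresholds are midpoints
  between consecutive distinct marker values whose split leaves at
  least `floor(min_group_frac * n)` samples per side
  (`min_group_frac = 0.10` by default; unconstrained scans select
  degenerate one-sample groups). The selected threshold maximizes the
  log-rank chi-square; ties break toward the smallest threshold for
  determinism. Because the statistic is maximized over thresholds, the
  naive chi-square p-value is strongly anti-conservative; the package
  always reports it (it is what the original analysis used) alongside
  an optional permutation-adjusted p obtained by re-running the entire
  scan on marker values permuted against the (time, event) pairs, with
  `p_adj = (1 + #{perm max chi2 >= observed}) / (B + 1)`. The default
  is B = 1,000 permutations.
* **Cox proportional hazards.** Newton-Raphson maximization of the
  partial likelihood with step-halving, so the log-likelihood is
  nondecreasing across accepted steps. Efron's tie correction is the
  default (Breslow selectable); without ties the two coincide.
  Standard errors come from the inverse observed information; CIs and
  p-values are Wald-based at 95 %. A coefficient whose magnitude
  exceeds 20 on the log-hazard scale with the likelihood still
  plateauing is reported as a monotone-likelihood error (perfect
  separation of event orderings), rather than returned as a spuriously
  "converged" estimate.
* **Stratified analysis.** The end-to-end routine filters the cohort on
  clinical fields (site, histotype), dichotomizes the chosen gene at
  its optimal cut-point, and fits univariate (high/low indicator) and
  multivariate Cox models. Grade (1-3) and FIGO stage (I-IV mapped to
  1-4) enter the multivariate model as ordinal numeric scores; the
  original analysis states only that grade and stage were "added", so
  ordinal coding was chosen as the most parsimonious encoding
  consistent with that description.

## Expression analytics

The GEO Series Matrix reader handles the "!"-prefixed key/value header,
the `!series_matrix_table_begin/end`-delimited tab-separated table, and
`!Sample_characteristics_ch1` lines of the form `key: value` (the key
map is configurable). Parse errors (missing markers, ragged rows,
duplicate sample columns) carry line numbers. Values such as `null` are
treated as missing and propagate into pairwise-complete correlation
counts. Matrices declared linear-scale are log2-transformed on read;
normalization itself (MAS5/RMA) is out of scope — the reader accepts
already-normalized matrices.

Probe-level matrices collapse to gene symbols by keeping, per gene, the
probe with the highest mean across samples (`max_mean`; `first` is also
available). No collapsed value is ever invented: every output row is an
input row.

The correlation panel computes Pearson r of each CA driver gene
(CCNA2, CDK1, NEK2, AURKA, MYCN, CCNE2, STIL, LMO4, PLK4, MDM2, CEP63,
E2F1, E2F2, E2F3, CEP152, PIM1, PIN1, CCND1) against the KIFC1 anchor,
with two-sided p from the t distribution on n-2 df, sorted by
descending r. Raw p at 0.05 is the primary significance call, matching
the original analysis; a Benjamini-Hochberg `bh_q` column is emitted in
addition and labeled as an extension.

The cumulative centrosome amplification index (CAI) is the per-sample
sum of log2 expression over a small centrosome panel. Two presets ship
because the source analysis describes two: `results`
= {CETN2, TUBG1, PCNT2, PLK4, CCNE1} and `methods`
= {PLK4, AURKA, AURKB, CCNE1, CETN2, TUBG1, PCNT}. The package does not
adjudicate between them; missing panel genes are reported, never
imputed.

## Gene-set enrichment analysis

Samples are stratified into KIFC1-high/low phenotypes either at the
median or at the optimal survival cut-point (the original procedure).
Genes are ranked by signal-to-noise, `(mu_h - mu_l)/(sigma_h +
sigma_l)`, with each class SD floored at `0.2 * |class mean|` and at an
absolute minimum of 0.2 when the mean is zero — the floors prevent
near-constant genes from dominating the ranking. The enrichment score
is the signed maximal deviation of the weighted KS running sum
(increments `|r|^p / sum |r|^p` at hits, decrements `1/(N - N_h)` at
misses; `weight_p = 1` by default, `0` gives the classic KS statistic).
The null is built from phenotype-label permutations (default 1,000),
which preserves gene-gene correlation; the NES divides each ES by the
mean absolute same-sign permuted ES of its own set, the nominal p is
the same-sign permutation tail with a +1 correction, and the FDR q
compares the pooled same-sign permuted NES tail with the observed NES
tail, capped at 1 and made monotone in |NES|. Significance is declared
at FDR q < 0.25 with nominal p < 0.05.

## Synthetic cohorts

The simulator generates what the analysis assumes:

* **Expression** is multivariate Gaussian on the log2 scale (default
  mean 7, SD 1 per gene, typical of normalized one-channel arrays).
  Only KIFC1-anchored correlations are prescribed (defaults follow the
  published pattern, e.g. r = 0.62527 for CCNA2 and 0.60066 for NEK2;
  CEP63 and CCND1 have no published value and default to 0), so the
  implied inter-gene structure follows a one-factor co-expression
  model, `corr(g_i, g_j) = r_i r_j`, which is always positive definite
  and reproduces the anchored correlations exactly. This matters: the
  published correlation strengths are jointly infeasible if the panel
  genes are forced mutually independent (the "star" structure), and the
  package raises a targeted error naming the worst-moved pair if a user
  requests a star pattern that nearest-positive-definite repair
  (eigenvalue clipping at 1e-8, diagonal rescaling) cannot honor within
  0.01.
* **Survival** follows a proportional-hazards model: exponential event
  times with hazard `lambda0 * exp(beta * z)` where z is the z-scored
  KIFC1 value (so `beta` has a scale-free, per-SD meaning; the default
  is log 2.14, the published univariate effect), and independent
  exponential censoring. Defaults `lambda0 = 0.02/month` and censoring
  rate `0.0225/month` were chosen once to give a median OS of a few
  years and an event fraction of ~47 %, the published cohort's death
  rate; no survival distribution is stated in the source, so the
  exponential choice is the simplest PH-consistent one.
* **Clinical covariates** (histotype, site, grade, stage) are drawn
  from the published cohort's frequency tables; they are independent of
  expression except through an optional grade-to-KIFC1 mean shift
  (`grade_kifc1_shift`, default 0) that emulates the reported rise of
  KIFC1 with grade without asserting an unpublished joint model.
* **IHC fields** are multinomial draws over intensities 0-3 per field,
  with grade-specific intensity distributions.

One `numpy` Generator seeded once per cohort drives all draws in fixed
order (grade, stage, site, histotype, expression, survival), so cohorts
are bit-reproducible per seed.

What the simulator does **not** emulate: probe-level intensities and
normalization artifacts, non-proportional hazards, informative
censoring, batch effects, non-Gaussian expression tails, or any direct
dependence of survival on grade/stage. Passing recovery tests therefore
demonstrates correctness of the estimators under the assumed model, not
robustness to real-data violations of it.

## Problem sizes and numerical choices

* Cox convergence: log-likelihood change < 1e-9 and sup-norm gradient
  < 1e-5; the acceptance cross-check tightens this to 1e-12 and runs
  the reference implementation at precision 1e-11 so the two optimizers
  agree to 1e-6 in beta.
* Parameter-recovery simulation: 200 replicates of n = 500 (mean
  recovered HR within +/- 0.15 of 2.14; CI coverage 0.92-0.98).
* Cut-point null calibration: 1,000 replicates at n = 150 with B = 199
  permutations per replicate — B = 199 gives the adjusted p a
  granularity of 0.005, an order of magnitude finer than the +/- 0.02
  calibration band being checked, while keeping the simulation
  desk-scale; the library default for a single analysis remains
  B = 1,000.
* Correlation recovery: one cohort of n = 10,000 (sampling SD of r is
  about 0.006-0.01 there, against a +/- 0.03 band).
* GSEA checks: 200 random small instances against a brute-force
  running-sum oracle; 60 null cohorts (36 samples, 120 genes, 100
  permutations) for p-uniformity; 20 planted-effect cohorts (60
  samples, 220 genes, 20-gene planted set shifted by 1.2 log2 units,
  200 permutations) for the positive control.

## Known limitations

* The maximally selected cut-point's naive p-value is reported because
  it is what the original analysis used; it should not be interpreted
  at face value (the package's own calibration shows it rejecting a
  true null ~8-9x too often at n = 150).
* Reproducing the published cohort numbers (univariate HR 2.14,
  multivariate HR 2.6, n = 154 primary serous) requires the deposited
  GEO series GSE9899, which is not bundled; the pipeline accepts its
  series-matrix file directly.
* The per-tissue intensity score surrogate (modal positive intensity)
  can differ from a pathologist's call on borderline tissues.
* FDR q-values from permutation pooling are coarse below ~1/B and
  should be read as estimates, not exact tail probabilities.
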