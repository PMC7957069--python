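# Methods

This note records the models, numerical choices and defaults behind each
pipeline stage, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the construction was
genuinely open. No empirical claim is made here that the test suite or
`scripts/acceptance.py` does not itself compute.

## Deconvolution

Each bulk sample's marker-gene vector **b** is regressed on the signature
basis **S** (marker genes × 22 leukocyte types); negative coefficients are
set to zero and the remainder renormalized to the simplex, so outputs are
relative proportions only.

* `nu-svr` (default): linear-kernel ν-support-vector regression over the
  grid ν ∈ {0.25, 0.5, 0.75}, keeping the fit with the lowest
  reconstruction RMSE. The signature is standardized by its global
  mean/sd and each mixture vector by its own mean/sd, which makes the
  estimate exactly invariant to rescaling the bulk matrix.
* `nnls`: non-negative least squares on raw linear values — a
  dependency-light fallback that is exact on noiseless identifiable
  mixtures (recovered to < 1e-6 in the tests).

Genes in the signature but absent from the bulk matrix are dropped and
logged; below 50 % marker overlap the run aborts. Per-sample permutation
p-values are out of scope (point estimates only, relative mode).

## Consensus clustering and K selection

For each K in the configured range (default 2–5), samples are subsampled
without replacement (fraction 0.8, 100 repetitions) and partitioned by
K-means (k-means++ initialization, Lloyd iterations, best of 10 inner
restarts); the consensus matrix is the co-clustering count divided by the
co-sampling count. Final labels cut the average-linkage tree of
1 − consensus at K.

Stability is the proportion of ambiguous clustering,
PAC = CDF(0.9) − CDF(0.1) of the off-diagonal consensus entries. K is
chosen as the **largest** K whose PAC lies within `pac_tol` (default
0.01) of the minimum — equally crisp solutions resolve toward the finer
grouping. The within-cluster SSE (elbow) curve is written for diagnostics
but never enters the decision, because elbow inflections are typically
ambiguous on these data. Repetition count and subsample fraction are
conventional consensus-clustering defaults and are exposed in the config.

## Differential expression

Expression is tested on the log2(x + 1) scale. Per gene, the pooled
two-sample t ingredients are moderated by empirical Bayes: under the
hierarchical model s²|σ² ~ σ²χ²_d/d with a scaled-inverse-χ² prior on σ²,
the marginal of the gene-wise sample variances is s₀²·F(d, d₀); matching
its first two moments gives closed-form (d₀, s₀²)
(d₀ = (4cd + 2d − 4)/(cd − 2) with c the squared coefficient of variation
of the sample variances; cd ≤ 2 ⇒ infinite prior df, complete shrinkage).
The moderated statistic uses s̃² = (d₀s₀² + ds²)/(d₀ + d) with d + d₀
degrees of freedom, and Benjamini–Hochberg adjustment runs across all
tested genes. Genes constant within both groups are flagged and assigned
p = 1.

DEG thresholds are strict: adjusted p < 0.05 **and** |log2FC| > log2(1.5)
(the subtype-level DE comparisons use adjusted p < 0.01, with
|logFC| > 1 for mRNA). With K > 2 classes, DEGs are the union of
one-vs-rest contrasts.

Calibration and the large-sample agreement with the ordinary pooled t are
property-tested; note that genes in the extreme tails of the variance
distribution are exactly the ones moderation moves, so "agreement" is
asserted for the bulk (median, 90th percentile), not the maximum.

## Survival core

Written from the defining formulas (no survival dependency in the
library; `lifelines` is an independent oracle in the tests):

* Kaplan–Meier product-limit estimator; censored-only times reduce the
  risk set without steps.
* Mantel–Haenszel log-rank test with the hypergeometric variance.
* Univariate Cox proportional hazards by Newton–Raphson on the partial
  likelihood with the **Efron** tie correction (day-resolution survival
  data routinely carries ties); convergence |Δβ| < 1e-8 within 50
  iterations, standard errors from observed information, diverging
  estimates (monotone likelihood) reported as non-converged. A score test
  at β = 0 is exposed; for a binary covariate with untied times it equals
  the log-rank χ².
* Maximally selected rank statistics: per-subject log-rank scores
  a_i = δ_i − Λ̂(t_i) (Nelson–Aalen), candidate cutpoints at midpoints of
  consecutive distinct score values subject to `minprop` (default 0.1)
  on both sides, statistic |Σ_{score≤c} a_i| / √(m(N−m)/(N(N−1))·Σa²) —
  the conditional permutation standardization of the linear rank
  statistic. Ties in the maximum resolve to the lower cutpoint. An
  optional permutation p-value (seeded, default 1000 permutations when
  requested; the pipeline itself only needs the cutpoint) uses the
  identical statistic on permuted scores. The statistic is invariant
  under strictly monotone transforms of the score; the numerator equals
  the two-sample log-rank O − E at the split.

## TMEscore model

Signature genes come from a random forest (default 1000 trees) trained on
a stratified half of the cohort to predict the DEG-based sample classes,
with genes ranked by permutation importance of the held-out log-loss
(in-sample importances of a saturated forest are uninformatively flat).
The default retention rule fits a second forest on shuffled labels and
keeps genes whose importance exceeds the decoy mean + 1 sd; a `top-n`
rule is available.

Each retained gene is then screened by univariate Cox on log2(x + 1)
expression and assigned by the **sign** of β (magnitude never used).
The per-sample score is Σ log2(x + 1) over the score-positive set X minus
the same sum over the score-negative set Y.

**Orientation.** X holds the protective genes (β < 0) and Y the
hazard-increasing genes (β > 0). This is a deliberate design decision: the
construction's defining property — validated on external cohorts in the
literature this method descends from — is that TMEscore-high denotes the
immune-active, better-prognosis subtype, and in a hazard-driven cohort
that direction forces protective genes into the score-positive set.
Genes with non-convergent fits or β exactly 0 are excluded (logged);
genes with Cox p > 0.05 are kept but flagged low-confidence, since the
published construction applies no significance filter (`cox_p_max`
exposes one).

The cutpoint from the maxstat scan dichotomizes the cohort
(high ⇔ score > cutpoint). Validation transfer (`apply_model`) freezes
both the gene sets **and** the cutpoint — the stricter reading — and
requires ≥ 50 % of each gene set in the new matrix; re-estimating the
cutpoint on new data is available by re-running `dichotomize`.

## Characterization

* Cell network: all pairwise Pearson correlations between cell-type
  fractions (t-transform p-values); the `r_min` edge threshold (default
  0.2) is a display filter. Node prognostic direction comes from
  univariate Cox on each fraction (favorable ⇔ β < 0 and p < 0.05).
* Group comparisons (TIDE-like response score between subtypes, TMEscore
  by MSI status with MSI-L and MSS collapsed): two-sided Wilcoxon
  rank-sum, exact enumeration when n₁ + n₂ ≤ 20 without ties, otherwise
  the tie- and continuity-corrected normal approximation.
* TMB: non-silent mutations (Missense, Nonsense, Frame_Shift_Del/Ins,
  In_Frame_Del/Ins, Splice_Site, Translation_Start_Site, Nonstop) per
  38 Mb of exome; both the class list and the exome size are
  configurable, and samples absent from the MAF get TMB 0 with a flag.
* Mutation frequency: per gene, a 2×2 Fisher exact test (two-sided,
  hypergeometric-enumeration convention) of mutated-sample counts between
  subtypes, each sample counted once per gene; raw p is primary, a BH
  column is attached.
* VAF: per-mutation alt/depth ratios compared between subtypes by the
  same rank-sum machinery; genes lacking mutations in either subtype are
  skipped and flagged.
* ROC: AUC via the Mann–Whitney rank identity (ties count ½), curves from
  cumulative true/false-positive counts, and the paired AUC difference
  tested by DeLong's structural-components variance. A score compared
  against itself returns p = 1 by convention.

## Synthetic cohort

Defaults state the cohort the pipeline is designed for: n = 400 samples,
two equally sized latent subtypes, hazard ratio 2.5 for the unfavorable
subtype, ~30 % censoring.

* **Compositions**: Dirichlet with base concentration 5 per cell type;
  the "high" subtype adds 5 × shift (shift default 3) to CD8 T cells,
  activated mast cells and neutrophils, the "low" subtype to M0/M2
  macrophages — the immune-hot vs immune-cold contrast.
* **Expression**: signature · fractions on marker genes plus 1000
  background genes (log2 baselines uniform on [3, 9]) of which 100 carry
  a planted ±1 log2 effect between subtypes; multiplicative log-normal
  noise (σ = 0.1 on the natural-log scale), clipped at 0. Gene-level
  population parameters are driven by a separate `population_seed`, so
  cohorts with different sample seeds are draws from the same generative
  process — the setting a frozen-model transfer assumes.
* **Survival**: event times Exponential(h₀·exp(β·z)) with h₀ = 1/1500
  days⁻¹, β = log 2.5 and z the hazard-increasing subtype indicator
  (z = 1 for "low", so "high" survives longer); independent exponential
  censoring with its rate solved (Brent) to hit the target censoring
  fraction in expectation.
* **Mutations**: 200-gene panel including recurrent bladder-cancer
  drivers (TP53, TTN, RB1, KDM6A, FGFR3, PIK3CA, KMT2D, ...) with
  subtype-specific per-sample probabilities and planted subtype-specific
  VAF distributions for five of them; background counts are
  mixed-Poisson (Poisson given a per-sample Gamma rate, shape 3, means
  160/110) because plain Poisson at realistic means would separate the
  subtypes by several standard deviations of TMB, which real cohorts do
  not show. VAF ~ Beta(2, 2) scaled by a Uniform(0.4, 0.9) purity.
* **Response**: the responder flag is Bernoulli with logit
  1.5·z(composition) + 0.3·z(mutation load) — composition-driven, weakly
  TMB-driven — and the TIDE-like `response_score` is the negated logit
  plus N(0, 0.5) noise (lower = better predicted response). MSI-H
  probability increases mildly with the favorable subtype and mutation
  load.

What the generator does **not** emulate: gene–gene co-expression beyond
the mixture structure, batch effects, non-proportional hazards, copy
number, mutational contexts/signatures, and realistic marker-gene overlap
between cell types (markers are cleanly enriched by construction). A
green end-to-end test therefore establishes that the pipeline recovers
planted structure of this kind — not performance on any real cohort.

## Numerical conventions

All TSV output serializes floats at 10 significant digits (bit-stable
round trips). Every stage seed derives from the run seed through
`numpy.random.SeedSequence`, so one integer determines the whole run;
two runs with identical config hash identically. MAF coordinates are
recorded but never interpreted. Model JSON round-trips bit-exactly.

## Known limitations

* The deconvolution is relative-mode only; absolute abundances and
  signature construction from single-cell references are out of scope.
* The Cox screen is univariate by design (only the coefficient sign is
  consumed); confounding between correlated signature genes is not
  modeled.
* The maxstat permutation p-value is Monte-Carlo, not the asymptotic
  improved-Bonferroni bound; the pipeline itself consumes only the
  cutpoint.
* With K = 3 sample classes the DEG union of one-vs-rest contrasts is an
  assumption; the contrast scheme is configurable.
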