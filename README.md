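# tmescore

Tumor-microenvironment (TME) subtyping and scoring for bulk expression
cohorts, built for the bladder-cancer setting where immune composition
stratifies prognosis and predicted response to immune checkpoint
inhibitors.

The package reimplements the full model-construction sequence as a tested,
reusable pipeline:

1. **Deconvolution** — per-sample proportions of 22 leukocyte types from a
   marker-gene signature basis (nu-SVR with a ν grid, or NNLS).
2. **Cell analysis** — hierarchical clustering of cell types, pairwise
   Pearson correlations, and a cell network annotated with per-type
   overall-survival direction from univariate Cox fits.
3. **TME patterns** — consensus clustering (subsampled K-means) over the
   fraction matrix; K chosen by the proportion of ambiguous clustering
   (PAC), with near-ties resolved toward the larger K.
4. **Differential expression** — empirical-Bayes moderated t with
   Benjamini–Hochberg adjustment; DEGs at adjusted p < 0.05 and
   |log2FC| > log2(1.5).
5. **Signature genes** — random-forest classification of the DEG-based
   sample classes with permutation-importance ranking against a
   shuffled-label decoy threshold.
6. **TMEscore** — signature genes split by the **sign** of their univariate
   Cox coefficient (Efron ties, Newton–Raphson); per sample

   ```
   TMEscore = Σ_{g ∈ X} log2(x_g + 1) − Σ_{g ∈ Y} log2(y_g + 1)
   ```

   where X holds the protective (hazard-decreasing) genes and Y the
   hazard-increasing genes, so higher scores mean a more favorable,
   immune-active microenvironment.
7. **Dichotomization** — the maximally selected rank statistic (log-rank
   scores, conditional permutation variance) finds the optimal cutpoint;
   samples become TMEscore-high / TMEscore-low.
8. **Characterization** — Kaplan–Meier / log-rank survival by subtype,
   TIDE-like response-score and MSI comparisons (Wilcoxon rank-sum),
   per-gene mutation-frequency Fisher tests, variant-allele-fraction
   comparisons, tumor mutation burden (TMB), and a paired ROC comparison
   of TMEscore against TMB with the DeLong test.

Because the original cohorts (TCGA-BLCA, GEO validation series) are not
shipped, a first-class synthetic-cohort generator provides ground truth
for every stage: Dirichlet immune compositions with two latent subtypes,
mixture-based bulk expression with planted DEGs, exponential survival tied
to the latent subtype, and a MAF-style mutation table with overdispersed
mutation loads.

## Worked example

```bash
tmescore run --seed 1 --outdir out/
```

runs simulation → deconvolution → clustering → DE → scoring → survival →
characterization and prints the summary (also written to
`out/summary.json`):

```json
{
  "n_samples": 400,
  "tme_k": 2,
  "n_degs": 128,
  "class_k": 2,
  "n_signature_genes": 101,
  "n_score_positive": 50,
  "n_score_negative": 51,
  "cutpoint": 79.16409004863885,
  "n_high": 199,
  "n_low": 201,
  "logrank_p_high_vs_low": 1.089918076572553e-12,
  "auc_tmescore": 0.8325580232092837,
  "auc_tmb": 0.5923744497799119
}
```

Reading: PAC selected K = 2 TME patterns (PAC(2) = 0.0); 128 genes were
differentially expressed between them; the random forest reduced these to
101 signature genes, split 50 protective / 51 risk by Cox sign. The
maxstat cutpoint 79.16 divides the cohort into 199 TMEscore-high and 201
TMEscore-low samples; the high group has markedly better overall survival
(log-rank p ≈ 10⁻¹²), and TMEscore predicts the planted responder flag
far better than TMB (AUC 0.83 vs 0.59) — the qualitative behavior the
method is designed to show on an immune-driven cohort.

The same model can be frozen and transferred:

```bash
tmescore apply --expression validation_expr.tsv --model out/model.json \
               --clinical validation_clinical.tsv --out val_scores.tsv
```

Python API: `tmescore.run_pipeline(RunConfig(...))`, or the individual
modules (`tmescore.deconvolution`, `tmescore.clustering`,
`tmescore.diffexpr`, `tmescore.survival`, `tmescore.scoring`,
`tmescore.characterization`, `tmescore.simulate`).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline end to end on the default synthetic cohort
(n = 400) with all randomness derived from `--seed`, prints the run
summary, and writes the target report to `--out`.

## Layout

```
src/tmescore/      library (io, simulate, deconvolution, clustering,
                   diffexpr, survival, scoring, characterization,
                   pipeline, config, cli)
tests/             pytest suite incl. property-based acceptance tests
docs/methods.md    model assumptions, parameter defaults, limitations
scripts/           acceptance runner
```
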