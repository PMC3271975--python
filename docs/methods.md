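# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices, and the limitations of `leukorisk`.

## Study design being modeled

The pipeline assumes a case/control transcriptomic design: one *training*
dataset (monocytes from familial-hypercholesterolemia patients and healthy
controls) and one or more *test* datasets from other leukocyte cell types
(circulating T cells from the same subjects, whole white blood cells, and
monocyte-derived macrophages from independent subjects). Every sample has
a binary risk class — `high` for patients, `low` for controls — plus a
subclass (homozygous FH, heterozygous FH, atherosclerosis, control) used
for effect scaling. Expression values are log2-scale intensities assumed
to be already normalized; the loaders validate but never renormalize,
because upstream preprocessing is outside the package's scope.

## Stage 1 — differential expression

Per probe, a **pooled-variance (Student) two-sample t-test** with
n₁+n₂−2 degrees of freedom compares high vs low samples. Student rather
than Welch is the default because equal-variance testing was the standard
in microarray case/control work of this design's era; the scalar op can be
swapped for Welch by the caller if needed. Probes with zero pooled
variance are skipped with a logged count rather than failing the run.

P-values become **Benjamini–Hochberg step-up q-values** with π₀ fixed at 1
(monotonized by the cumulative minimum, via statsmodels). BH is
deterministic and conservative; Storey-type π₀ estimation is deliberately
not used. The discovery threshold is **inclusive**, q ≤ 0.01, so a probe
whose q-value rounds exactly to 0.01 is retained.

Fold changes are reported on the linear scale with the down-regulation
convention r = 2^(mean_high − mean_low), returned as −1/r when r < 1, so
|fold change| ≥ 1 always and the sign encodes direction.

## Stage 2 — functional triage

Proprietary pathway software is replaced by a plain annotation table
(probe → gene symbol → one category). The default allowed vocabulary is
the set of categories a curated atherosclerosis triage retains:

> Inflammatory Response, Inflammatory Disease, Immunological Disease,
> Lipid Metabolism, Other Metabolic Processes, Carbohydrate Metabolism,
> Hematological System Development and Function.

Flagged probes without any annotation are dropped with a logged count;
an empty result is an error that names the likely fix (review the allowed
categories). Filtering preserves the ascending-p discovery order, which
fixes the panel ordering for all downstream linear algebra.

## Stage 3 — COXEN concordance selection

For a panel of g probes, each dataset contributes a g×g **Spearman**
co-expression matrix. Probe i's concordance across two datasets is the
**Pearson** correlation r between its two co-expression vectors — row i of
each matrix with the self-entry removed (length g−1). Spearman within a
set, Pearson between sets, reflects the two roles: rank correlation is
robust for co-expression; the second-order comparison is of real-valued
correlation profiles. Significance uses the correlation t transform on
n = g−1 points, t = r·√((g−3)/(1−r²)) with df = g−3, two-sided, and
selection is strict, p < α with α = 0.001 by default. The p-values are
deliberately **not** multiplicity-adjusted: the method is defined by a
fixed per-gene threshold, and adjusting would change panel sizes.

Two numerical choices matter:

* **Diagonal exclusion.** Self-correlations are identically 1 in both
  sets and would inflate every concordance score.
* **Sample scope.** By default the pipeline computes co-expression on the
  **control (low-risk) samples only** (`coxen_sample_scope: controls`).
  With case/control data, every truly differential probe co-varies with
  the class label, which induces a strong disease-driven correlation
  between all differential probes *in both datasets*; computed on all
  samples, this shared component dominates the correlation vectors and
  makes constitutive co-expression — the thing COXEN is after —
  essentially unidentifiable. Restricting to controls isolates the
  constitutive network. The `coexpression_matrix` and
  `select_coxen_panel` operations accept `sample_scope="all"` (and
  default to all samples when no metadata is passed) for the
  unstratified variant.

With very few controls (the 5+5 whole-blood shape) the concordance
estimates are extremely noisy and few or no probes reach p < 0.001; the
pipeline logs such empty selections in the run manifest and skips that
test set's COXEN row instead of aborting.

## Stage 4 — the risk model

* **Standardization.** Each probe row is centered and scaled to unit
  sample variance (ddof = 1) *within its own dataset*. Test sets are
  standardized with their own statistics, never with the training set's,
  because each dataset was produced under different experimental
  settings. Constant rows become zeros with a warning. This makes the
  posterior scores invariant to any gene-wise affine rescaling of the raw
  test matrix.
* **PCA.** The top **three** principal components of the standardized
  panel (samples as observations, probes as variables; SVD-based). The
  component count is fixed at 3; the ≥ 70% cumulative-variance property is
  checked and logged as a warning when violated, but never changes the
  model — coverage is treated as an observed property, not a selection
  rule. Loading signs are fixed so each column's largest-magnitude entry
  is positive, making fits bit-reproducible.
* **LDA.** Two-class Gaussian discriminant with class means, pooled
  within-class covariance (divisor n−2), and **equal priors** by default —
  false positives and false negatives are weighted equally regardless of
  cohort imbalance; class-frequency priors are a config option. A
  near-singular covariance (possible with 6-gene panels and few samples)
  is ridge-regularized by ε = 10⁻⁶·trace/3 with a logged message. The
  model output is the posterior probability of the high-risk class, which
  for the shared-covariance two-class case reduces to a logistic function
  of a linear score.

## Stage 5 — evaluation

Group separation is tested with the same pooled t-test as discovery,
applied to posterior scores. The ROC is built over candidate cutoffs at
every observed score plus a +∞ sentinel (classify high when score ≥
cutoff); this grid attains every achievable confusion table. The operating
point maximizes the **Youden index**; ties are broken toward the cutoff
with **higher specificity** (fewer false positives in a screening
setting), then toward the larger cutoff. Sensitivity, specificity, PPV and
NPV follow from the confusion counts; a zero-denominator rate is reported
as absent with a warning rather than as NaN. Reports print rates in
percent to 1 decimal and Youden to 2 decimals. `metrics_from_rates`
inverts published sensitivity/specificity plus group sizes into integer
confusion counts (rounding half up) and derives PPV/NPV/Youden from them.

`wpgma_cluster` exposes the WPGMA/McQuitty agglomerative clustering
(average distance of the two merged members, robust to uneven cluster
sizes) on Euclidean distances of standardized rows or columns, as a
scipy linkage matrix.

## The synthetic cohort generator

Per cell type, on the log2 scale:

value(g, s) = μ_g + Σ_k λ_gk(cell)·f_ks + δ_g·z(s) + ε_gs

with μ_g ~ U(5, 9); sparse loadings (each probe on one of K = 5 latent
factors, magnitude 0.21, random sign); residual sd 0.09; planted effects
|δ| ~ U(0.26, 0.92) with random sign on 100 of 2000 probes (the ±1.2–1.9
linear fold-change range); z = 0 for controls, 1 for patients, ×1.8 for
homozygous FH (an ordinal severity bump, mirroring their clinically much
higher risk); and a concordant fraction (default 0.5) of probes keeping
their loadings across cell types.

Design choices that required judgment:

* **Discordance is a different factor.** A discordant probe is reassigned
  to a *different* latent factor (fresh sign) in each non-reference cell
  type. A fully random redraw would keep the same factor with probability
  1/(2K) (silently concordant) or merely flip the sign, producing strong
  *negative* concordance that a two-sided p < α rule would select; both
  would blur the planted truth.
* **Subjects own their factor scores.** Datasets that reuse the subjects
  of an earlier set (the monocyte/T-cell pair) reuse the same realized
  factor scores; only loadings (per cell type) and residual noise differ.
  The latent factors represent subject-level systemic biology, and this
  is also what makes concordance estimable from 13 control samples — with
  independent scores the Spearman sampling noise (variance 1/12) swamps
  the signal.
* **Noise scale.** loading 0.21 / noise 0.09 gives a within-group sd of
  ≈ 0.23 log2 units (microarray-realistic) chosen so that both hold at
  once: ≥ 70% of planted effects are recoverable at q ≤ 0.01 with 10 vs 13
  samples, and the within-control factor correlation (≈ 0.85) is large
  enough for COXEN to detect from 13 controls.
* **Annotations.** All differential probes are annotated, 20% with an
  out-of-vocabulary category so triage has something to drop; background
  probes are annotated with probability 0.5 from the full pool.

What the generator does **not** emulate: probe-level array artifacts,
batch and hybridization effects, non-Gaussian heavy tails, correlated
effect sizes, or any structure distinguishing the three high-risk
subclasses beyond the scalar severity multiplier. Passing tests therefore
demonstrate the pipeline's correctness and its behavior under the assumed
generative model, not performance on real arrays — on real data the
separation is far from the near-perfect classification seen on synthetic
cohorts.

## Calibration and test-design notes

* **Null p-value uniformity** is checked on p-values pooled across
  independent replicate cohorts. Within one cohort the factor model makes
  probes strongly dependent (blocks of ~400 probes share a factor), so a
  per-cohort KS test rejects even though each probe's marginal p-value is
  exactly calibrated; pooling across replicates is the valid test of
  marginal uniformity under dependence.
* **COXEN null calibration** uses two independent pure-noise datasets and
  a 1000-probe panel at α = 0.001, where the per-probe selection rate
  should be ≈ α (observed mean ≈ 0.5–1 selections, slightly conservative
  because the t transform is applied to rank-based correlation entries).
* **COXEN vs universal comparison.** Under the study conditions both
  panels usually classify the held-out cell type perfectly, so raw t-test
  p-values (~10⁻⁶⁰) differ only by saturation noise. The comparison is
  therefore made on the Youden index at the optimal cutoff — the scale on
  which the original analysis compares predictors — with a one-sided
  paired sign test across seeds. Seeds whose concordant selection is
  empty or smaller than the 3 probes a 3-PC model needs (~3% of seeds)
  count against the COXEN panel.
* **Problem sizes.** Simulation-based checks use 2000-probe cohorts and
  20–50 replicate seeds; these sizes give stable pass/fail behavior for
  the sign tests and calibration bands while keeping the whole suite fast
  on a single CPU.

## Known limitations

* The discovery counts of the original analysis (hundreds of flagged
  probes from 54,675) are not reproducible here: they depend on the
  original arrays and unstated preprocessing. The package reproduces the
  *method* and the internally consistent published confusion metrics, not
  the dataset-specific gene lists.
* Whether the original triage involved manual curation beyond category
  membership is unknowable; only category filtering is implemented.
* COXEN concordance from very small control groups is effectively
  uninformative; the pipeline surfaces this as a skipped row rather than
  guessing.
* No cross-validation, shrinkage discriminants, AUC confidence intervals,
  or clinical-covariate fusion — all outside the modeled analysis.
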