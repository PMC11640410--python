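# Methods

## Scope and model

`mirmeta` implements a multi-study miRNA differential-expression
meta-analysis with downstream target integration. The data model is k
independent two-group studies (resistant vs control) measured on different
platforms. For miRNA *i* in study *s* the true group difference is

    θ_is ~ N(μ_i, τ²),

i.e. a random-effects structure: μ_i is the consensus effect (0 for null
features) and τ² the between-study variance created by platform and cohort
differences. Observed log2 intensities add within-study noise N(0, σ²).
The pipeline estimates θ_is per study (moderated t), recovers its standard
error as SE = |logFC/t|, tests homogeneity with Cochran's Q, combines with
the DerSimonian–Laird (DL) moment estimator, and BH-adjusts the combined
normal-z p-values across all features tested.

Downstream, significant human DEMs are mapped through a validated
interaction table, intersected with the union of per-study DEG calls
(adj. p < 0.05 and |log2FC| > 1 for mRNA), and the overlap is carried into
hypergeometric over-representation, degree-based hub ranking on a
confidence-filtered protein-interaction graph, and two-group survival
comparison (Kaplan–Meier, log-rank, O/E hazard ratio).

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| alpha | 0.05 | — | FDR level for DEM/DEG calls and enrichment |
| lfc_cut | 1.0 | log2 | mRNA fold-change cutoff; miRNA meta-calls use adj. p only |
| model | random | — | always-random-effects; `q-gated` switches to fixed when Q_p ≥ 0.05 |
| kappa | 0.96 | — | term-grouping agreement threshold |
| min_score | 0.4 | — | STRING-style medium-confidence edge cutoff |
| d0, s0² | estimated | — | variance-prior moments (closed forms on log s²); d0=0 disables shrinkage |
| impute tol / max_iter | 1e-4 / 10 | — | normalised-change stopping rule of the iterative imputer |

Synthetic generator defaults (the study conditions all calibration numbers
refer to): 3 miRNA studies of 300 features, 10 samples per arm, 20 planted
DEMs with |μ| = 2 log2 units, τ² = 0.05, σ² = 0.25, 5% MCAR missingness, 10%
non-"hsa" decoy features; 3 mRNA studies of 1000 genes with 90% of planted
targets truly DE (sign opposite their miRNA) plus 30 independent DE genes;
~4 planted targets per DEM; survival n = 200, baseline hazard 0.02/month,
planted log-HR ln 2, uniform administrative censoring on [0, 120] months.
These sizes mirror a small multi-platform microarray meta-analysis: modest
arms, strong planted effects, mild heterogeneity.

## Numerical and design choices

* **Effect scale.** The combined effect is the log2 fold change with
  SE = |logFC/t|; a Hedges-g standardised-mean-difference scale is available
  (`effect="smd"`) since the two conventions differ only by the pooled-SD
  scaling in a two-group design.
* **SE source.** By default the moderated t is used to derive study SEs
  (`use_moderated=False` selects the ordinary t). With zero t the feature is
  excluded from that study with a logged count; features present in fewer
  than two studies are dropped from the combination.
* **DL degeneracy.** τ² is truncated at 0; with equal weights the DL
  denominator is w(k−1) > 0, and the k ≥ 2 rule excludes the degenerate
  case. When τ² = 0 the random-effects estimate reduces exactly to the
  inverse-variance fixed-effect estimate.
* **z reference.** The combined z is treated as standard normal; no small-k
  df correction (Hartung–Knapp) is applied.
* **Moderation.** Prior estimation follows the method of moments on
  log s²; the trigamma inverse is solved by Newton iteration. A negative
  moment estimate of trigamma(d0/2) yields d0 = ∞ (all variances equal the
  prior); zero-variance zero-logFC features get p = 1.
* **Imputation.** MissForest-style: initialise with feature means, then
  regress each feature with missing entries on all others (random forest
  with 100 trees by default; ridge and plain mean as cheaper options),
  visiting features by descending missingness (ties by id), until the
  normalised change γ = Σ(new−old)²/Σnew² over imputed cells drops below
  tol. The regressor seed is fixed per feature across sweeps so the update
  is a deterministic fixed-point iteration; non-convergence logs a warning
  and returns the last iterate. Observed cells are never modified.
  Imputation is applied after log2 transformation.
* **Intersection.** DEG lists are aggregated by union by default
  (`intersection` and `majority` modes available); no miRNA–target direction
  consistency filter is applied by default.
* **Enrichment.** Universe = all genes in the collection; the upper tail
  includes the observed count (P(X ≥ k)). Bonferroni is the default for GO
  categories, BH for pathway collections, Holm available as the step-down
  variant. Kappa grouping uses single-linkage over pairwise Cohen's kappa of
  membership vectors (identical memberships define kappa = 1, including
  degenerate all-in/all-out pairs); each group is labelled by its most
  significant term. The iterative merge heuristics of interactive annotation
  tools are deliberately not reproduced — single linkage is deterministic
  and testable.
* **Survival.** Median split by default; `best_cutoff` scans the inner 80%
  of expression values and reports the minimising cutpoint's p uncorrected
  (flagged in the log). Censored subjects at an event time remain at risk
  for that time. The hazard ratio is the log-rank O/E approximation, not a
  Cox partial-likelihood estimate; a group with zero events leaves HR
  undefined (NaN) with a warning.
* **Determinism.** Every generator and the pipeline draw from named
  substreams of one root seed; equal seeds give byte-identical outputs.

## Calibration experiments and their designs

`mirmeta.experiments` (used by the test suite and `scripts/acceptance.py`)
measures the operating characteristics at these problem sizes, chosen so the
whole battery runs in about two minutes on one CPU:

* **Null type-I of the combination** — 10,000 null features through the full
  per-study fit at k = 3. Study SEs here are derived from the ordinary
  two-sample t. Reason: under the generator's homogeneous-variance null the
  variance prior degenerates to d0 = ∞ and moderated SEs become essentially
  exact; with exact SEs the DL + normal-z test at k = 3 is mildly
  conservative (measured ≈ 0.037, because τ̂² > 0 half the time under the
  null). Ordinary-t SEs retain the finite-df sampling noise that study SEs
  carry in practice — on real heterogeneous-variance data the moderated
  total df d0 + df is finite — and in that regime the test is calibrated
  (measured ≈ 0.048).
* **Cochran-Q moments** — 10,000 homogeneous effect triples with *known*
  SEs, the setting in which Q ~ χ²(k−1) is exact; estimated SEs inflate
  E[Q] by ≈ ν/(ν−2) for ν-df variance estimates, so the χ² reference is
  checked where it is the correct sampling distribution.
* **DL closed-form agreement** — 100 random effect tables vs an
  independently coded plain-Python implementation of the closed forms.
* **τ² recovery** — k = 20 studies, planted τ² = 0.5, 200 features,
  SEs U(0.1, 0.3); median DL estimate.
* **Moderated-t calibration** — 5,000 null features with true variances
  drawn from a scaled inverse-χ² prior (d0 = 4); KS test of p-value
  uniformity, plus exact equality of the d0 = 0 statistic with the ordinary t.
* **BH FDR** — 50 replicates of a 10,000-feature mixture with 500 true
  effects (|z| shift 3); mean false-discovery proportion.
* **End-to-end recovery** — 20 full pipeline runs at generator defaults;
  fraction of planted DEMs called and of planted target-DEGs recovered in
  the intersection.
* **Enrichment ranking** — 100 replicates; how often the planted term (80%
  of the true overlap genes plus 10 fillers) ranks first.
* **Survival** — 1,000 null replicates (β = 0, n = 200) for log-rank size;
  200 replicates at β = ln 2 for the median O/E HR.
* **Imputation** — 10 replicates of 20 factor-correlated features × 50
  samples with 10% MCAR masking; masked-entry RMSE of the random-forest
  imputer vs column means.

## What the synthetic data does and does not emulate

The generator reproduces the statistical structure the analysis assumes:
two-group designs, shared effects with between-study variance, MCAR
missingness, species-prefix decoys, a miRNA→target→DEG causal chain,
partially enriched gene sets, a designated network hub, and exponential
survival with a group hazard ratio. It does **not** emulate
platform-specific probe effects, batch effects, miRBase version drift,
correlated features beyond the imputation benchmark, non-exponential
hazards, or informative censoring. Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery under the assumed
model, not the biological validity of any particular public-data result; in
particular, published headline counts and hazard ratios from real cohorts
depend on external databases and are outside what synthetic data can check.

## Known limitations

* The normal-z combination at very small k is conservative when SEs are
  near-exact (see above); a t-reference or Hartung–Knapp adjustment is not
  implemented.
* The O/E hazard ratio is slightly biased toward the null relative to a Cox
  estimate (measured median ≈ 1.9 for a true HR of 2 at n = 200).
* `best_cutoff` dichotomisation inflates significance and is reported
  uncorrected, by design, with a log flag.
* BH re-adjustment of already-adjusted p-values is not a no-op (the step-up
  multiplies by m/j again); adjusted values should not be fed back in.
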