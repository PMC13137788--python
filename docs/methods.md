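# Methods

## The mutation-intolerance contrast

Tumors are under selection: a gene whose disruption is tolerated in healthy
tissue but never observed mutated in tumors is a candidate *mutation-
intolerant gene* (MIG) — a gene the tumor cannot afford to lose. The
framework quantifies this per gene in a matched tumor–healthy tissue pair:

1. **Per-cohort significance.** Each cohort's per-gene nonsilent mutation
   count is tested against a cohort-wide neutral background. The built-in
   engine is deliberately simple — a uniform nonsilent rate per base per
   sample, estimated as total nonsilent mutations over total coding length
   times cohort size, with the gene's exact one-sided binomial tail
   `P(X >= observed)` as the p-value (Poisson tail for very large trial
   counts). The framework is engine-agnostic: per-gene p-values from a
   covariate-aware external tool can be substituted and flow through
   unchanged.

   *Robust background.* The neutral rate is estimated with iterative
   outlier exclusion: genes whose counts are extreme against the current
   rate (upper-tail p below 0.01/n_genes) are removed and the rate
   re-estimated until stable (at most 5 rounds). Without this, a few
   highly mutated genes inflate the background substantially (about 2x in
   the planted synthetic cohorts) and mask true mutation tolerance. Under
   a pure null the exclusion removes ~0 genes, so calibration is
   unaffected.

2. **Pairing and combination.** Healthy-tissue tolerance is the healthy
   p-value P_H; tumor intolerance is 1 − P_T. Both are clamped to
   [eps, 1] (eps = 1e-12) because P_T = 1 is routine for tumor-unmutated
   genes. The two are combined by Fisher's method,
   `stat = −2 (ln p1 + ln p2)`, referred to a chi-square upper tail with
   2k = 4 degrees of freedom. A `fisher_df` override exists for
   replicating variant published df conventions. Combined p-values are
   Benjamini–Hochberg adjusted (step-up with cumulative minimum; ties get
   equal q).

3. **MIG call.** A gene is a MIG when combined FDR < 0.1 AND its mean
   CRISPR dependence score over lineage-matched cell lines exceeds 0.9
   (both strict). Scores follow the probability-of-dependency convention
   (higher = more essential); an inversion flag accommodates effect-score
   matrices. Genes without any matched line are flagged, never called.

4. **Top-MIG triage.** Three strict rules: tumor FDR > 0.6 (no tumor
   enrichment), healthy FDR < 0.1 (tolerated in healthy tissue), and log2
   mutation-burden ratio > 1, where
   `MBR = ((c_H + 1)/n_H) / ((c_T + 1)/n_T)` with a pseudocount of 1 on
   counts so tumor-mutation-free genes stay defined. Ranking is by MBR
   descending, ties by combined p then gene symbol, so output order is
   deterministic.

## Enrichment statistics

Set enrichment against synthetic-lethal (SL) pair lists uses two
statistics — members appearing in any SL pair, and SL pairs fully inside
the set — compared to random same-size gene sets, optionally matched on
log-variance deciles of expression. Permutation p-values carry the
add-one (Phipson–Smyth) correction, p = (n_ge + 1)/(n_iter + 1), so p = 0
is unreachable and the floor at 10^6 iterations is 1e-6. Drug-target-style
enrichment uses the exact hypergeometric upper tail. Co-expressed pairs
are Pearson |r| > 0.5 with a two-sided t-based p < 1e-8, both strict;
constant genes are excluded.

## Prognostic score

Given a candidate gene list (in the motivating application, cell-cycle
MIGs), a lasso Cox model selects genes per cancer type. Fitting is
delegated to the coordinate-descent Cox-net solver (scikit-survival);
the penalty grid comes from the full-data path and 10-fold
cross-validation picks the alpha maximizing held-out Breslow log partial
likelihood (the lambda-min rule). Expression is z-scaled per gene inside
the fit; means and scales are stored in the model metadata and re-applied
at scoring, so the reported score is exactly the fitted linear predictor:

    score_i = sum_g coef_g * z(expr_{i,g})

Patients are split at the median score; ties go to "low" (conservative
toward the high-risk call). Survival separation is tested with the
two-group Mantel–Haenszel log-rank test (lifelines), chi-square on 1 df.
Time-dependent AUC / concordance estimators are out of scope.

## Screen phenotype caller

Cells from a pooled base-editing screen with single-cell readout pass QC
when genes detected > 500, total UMIs > 300, mitochondrial percentage
< 10, and exactly one sgRNA is assigned (all strict). Guide effects on
fitness come from a logistic GLM over (cell, candidate-guide) observation
units restricted to the target guide plus all non-targeting controls:

    logit(p) = b0 + b1 * I_gRNA + b2 * log F_D0

Because covariates are constant within a candidate guide, the model is
fitted on the equivalent aggregated binomial data (identical likelihood,
hundreds of times faster). b1 is the target-vs-control log-odds shift
after adjusting for Day-0 library abundance; the p-value is the
likelihood-ratio test against the b1-free model on 1 df, converted to
log2FC = b1/ln 2, and BH-adjusted across tested guides at FDR < 0.05
(negative log2FC = depleting/lethal, positive = enriched).

*Why log F.* Library frequency acts multiplicatively on a cell's odds of
carrying a guide: under a no-effect screen, carriage log-odds are linear
in log F_D0. Entering F untransformed leaves curvature that the target
indicator absorbs, inflating the measured type-I error from ≈0.050 to
≈0.058 at realistic per-guide coverage (~230 cells/guide; 3000-draw
simulation). The untransformed form (`method="linear"`) and a fixed
logit-offset variant (`method="offset"`) remain available and must agree
in sign.

*Separation.* A guide absent from every endpoint cell (or any fit with
boundary fitted probabilities) is refit with Firth's Jeffreys-prior
penalization, which keeps the estimate finite and the depleting sign
reported; such effects are flagged `separation`, never silently reported
as unpenalized estimates. Guides with fewer than 50 informative cells are
flagged `low_cells`, excluded from the BH family, and reported untested.

## Synthetic data: the stated world

The generators produce every input the pipeline reads, with planted truth.
They emulate statistical structure only, not biology:

- **Cohorts** — per-gene mutation counts are Poisson with rate
  `background * multiplier * length * n_samples`, spread uniformly over
  samples; 30% of mutations are silent. Defaults: 100 genes of 500–3000
  bp, 500 samples per cohort (the per-tissue scale of pan-cohort
  datasets), background 2e-6 mutations/bp/sample. Planted MIGs carry a
  10x healthy multiplier and 0 tumor rate; planted tumor drivers the
  mirror image. No hotspot, signature, or copy-number structure exists —
  a green recovery test establishes that the statistics behave, not that
  real cohorts are this clean.
- **Dependence** — Beta scores with concentration 50; essentials at mean
  0.95, nulls at 0.30, so a planted essential's 10-line mean clears 0.9
  with probability > 0.99.
- **Survival** — exponential event times with log-hazard linear in
  standard-normal expression; uniform censoring with the horizon solved by
  bisection so the realized censored fraction lands within ±5% of the
  request.
- **Screens** — latent library composition is symmetric Dirichlet with
  concentration 50 (frequency CV ≈ 14%, a tightly cloned library); Day-0
  counts are one multinomial read-out at 100k reads; endpoint cells are
  assigned multinomially with odds proportional to the *normalized Day-0
  frequency* times per-guide fitness (controls fixed at 1), matching the
  quantity the model conditions on. QC covariates are drawn so ≈90% of
  cells pass; 4% of cells receive a second guide and are QC-removed.

All randomness flows from one spec-level seed through independent named
substreams (CRC32 of the stream name as the spawn key), so every generator
is a pure function of its spec across processes.

## Numerical choices and degenerate inputs

- Binomial tails switch to the Poisson limit only above 10^6 Bernoulli
  trials (configurable); both paths agree to ~1e-3 relative at the switch.
- BH is shared by every stage; NaN p-values are rejected, never dropped.
- Fisher combination rejects p = 0 (the eps clamp upstream makes it
  unreachable) and empty lists.
- Median-split ties go to "low"; constant scores raise rather than
  produce an empty group.
- Unknown variant classes become `unknown` and never reach counts; strict
  mode escalates them to parse errors.
- GLM fits use IRLS to tolerance 1e-8, max 100 iterations; LRT statistics
  are floored at 0.

## Known limitations

- The built-in significance engine ignores covariates (replication timing,
  expression, chromatin), mutation spectra, and indel/SNV distinctions; on
  real cohorts it will miscalibrate for genes with atypical local rates.
  Use the external-p-value path with a covariate-aware engine there.
- The triage's healthy-tolerance rule (FDR < 0.1) is underpowered for
  short genes at desk-scale cohort sizes — in the synthetic world ~6% of
  planted MIGs (the shortest) miss it; the analogous real-data behavior is
  tissues too small to evaluate reliably.
- The screen GLM's chi-square reference retains a small (<1 percentage
  point) type-I excess at low per-guide coverage; effects measured from
  fewer than ~50 cells are flagged instead of tested.
- Multi-pair meta-combination across tissue pairs is a thin second Fisher
  pass; no heterogeneity modeling is attempted.
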