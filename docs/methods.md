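# Methods

This note documents the statistical model, the defaults and the design
choices behind `myelinlfq`, and what the synthetic-data generator does
and does not emulate.

## Data model and pipeline order

A quantification experiment is a proteins × samples intensity matrix
with explicit missingness (`NaN`) and a scale tag (`raw`, `log2`,
`normalized`), plus a sample design mapping samples to groups with
optional pairing ids. The aging (unpaired) pipeline runs:

1. detection filter,
2. log₂ transform,
3. missingness classification + imputation,
4. quantile normalization,
5. moderation-prior fit + moderated t-test,
6. FDR adjustment,
7. relative-abundance shares and the fold-change-versus-abundance
   correlation.

Each stage logs proteins in/out; a stage can only drop proteins, never
invent them, and the run log plus the full effective configuration are
part of every report.

## Detection filter

A protein is *detected in a group* if it has at least `min_detected`
(default 2, with groups of 3) non-missing values in that group, and is
retained if detected in at least one group. Retained proteins are
labelled `both`, `<group>_only`, or `excluded`. Requiring detection in
*both* groups would make one-group-only proteins unreportable, yet such
proteins are a real and interesting outcome of this kind of comparison
(proteins present only in young or only in old fractions), so presence
in a single group suffices for retention. This interpretation is a
deliberate design choice and is recorded in the presence labels.

## Missingness classification

Label-free data mix two missingness mechanisms: intensity-dependent
left-censoring (low-abundance peptides falling below the detection
limit — missing not at random, MNAR) and sporadic, intensity-independent
losses (missing at random, MAR). Classification is per protein and per
two-group comparison, from the replicate presence pattern alone:

* `COMPLETE` — no missing values;
* `MNAR` — at least `mnar_min_missing` missing in one group **and** at
  least `mnar_min_present_other` observed in the other (the depleted
  group is recorded);
* `MAR` — at most `mar_max_missing` missing per group, not qualifying
  as MNAR;
* `FILTERED` — fewer than 2 observed values in both groups, or any
  other pattern (uninformative; dropped with an audit record).

The thresholds are a `MissingnessRule` parameterized by group size. The
classical statement of this rule is written for groups of five
replicates (MNAR: missing in ≥3/5 of one group, present in ≥3/5 of the
other; MAR: ≤2 missing per group). The designs handled here have three
pools per group, so the shipped n = 3 default is the proportional
transcription: MNAR = missing in ≥2/3 of one group and present in 3/3
of the other; MAR = at most 1 missing per group; FILTERED as above.
This transcription is an interpretation, not a measured property of any
particular dataset, and the rule object makes the thresholds explicit
and overridable. The classification is verified against an exhaustive
enumeration of all 2⁶ presence patterns.

## Imputation

* **MinDet** (MNAR cells): the missing cell receives the minimum
  observed value of its own sample column — a detection-limit surrogate
  for left-censored values. Imputation operates on log₂ intensities
  (the convention of the left-censored imputation literature; the
  choice is config-switchable).
* **knn** (MAR cells): candidate neighbours are the other protein rows
  with an observed value in the target column; distance is Euclidean
  over the columns observed in both rows; the imputed value is the mean
  of the k = 10 nearest candidates' values in that column. Equidistant
  neighbours are ordered by protein id so imputation is deterministic.
  If fewer than k candidates exist, all are used and a warning is
  logged. The implementation is intentionally bespoke: the exact
  neighbour semantics and deterministic tie-break above are part of the
  contract, and generic imputers rescale distances by the fraction of
  jointly observed columns, which changes results.

Observed cells are never altered (cell-exact test), and every imputed
cell is recorded in the audit table with its mechanism and value.

## Quantile normalization

All columns are forced onto the common distribution of sorted-row
means; within-column rank order is preserved. It requires a complete
matrix and therefore must run after imputation — calling it earlier is
a hard error, not a warning.

## Moderated t-test

Per protein, with groups of size n₁, n₂ and df = n₁+n₂−2:

    s²_post = (d₀ s₀² + df s²) / (d₀ + df)
    t_mod   = log₂FC / sqrt(s²_post (1/n₁ + 1/n₂)),  referred to t(df + d₀)

The prior (d₀, s₀²) is estimated by moment-matching on log sample
variances: under s² ~ s₀²·F(df, d₀) the mean and variance of log s² are
closed forms in digamma/trigamma, so matching the empirical moments and
inverting trigamma numerically (Newton, tolerance 1e-10) recovers the
prior. If the empirical spread of log s² does not exceed the expected
sampling spread, the prior is reported as d₀ = ∞ with s₀² at the
bias-corrected geometric-mean location and every posterior variance
equals s₀². Fractional df_total is handled by the regularized
incomplete-beta tail of the t distribution (scipy). The whole chain —
prior, posterior variances, t, p — is cross-checked in the test suite
against Bioconductor limma (`lmFit` + `eBayes`) at 1e-10 relative
tolerance; limma remains an oracle only, never the implementation.

Conventions: log₂FC = second group minus the design's first (reference)
group — old − young, crush − intact; all tests are two-sided;
zero-variance proteins get p = 1 and an explicit flag rather than being
dropped.

## Paired test and FDR

The injury comparison is a two-sided paired t-test on within-pair log₂
differences (df = number of complete pairs − 1); pairs with a missing
member are dropped per protein, and proteins with fewer than 2 complete
pairs are flagged `dropped`. Constant nonzero differences are
degenerate (flagged, p = 1); all-zero differences give t = 0, p = 1.

q-values: Benjamini–Hochberg step-up (default), or Storey's estimate,
implemented as BH scaled by π̂₀ from the λ-grid smoother (π̂₀(λ) =
#{p > λ}/(m(1−λ)) on λ = 0.05…0.95, cubic-spline smoothed, evaluated at
the largest λ, clipped to (0, 1]). The differential-expression
criterion in all reports is q < 0.05. The original analyses of this
data type often use a local-FDR tool for the unpaired comparison; that
density-estimation machinery is deliberately out of scope here, so DEP
lists may differ marginally — the report header states this.

## Enrichment statistics

* **Ground probability**: the fraction of all quantified proteins with
  sign(log₂FC) in the requested direction and q < α. Using the
  analysis's own universe makes the binomial null empirical rather than
  hypothetical.
* **Binomial subset test**: one-sided upper tail P(X ≥ k | n, p₀) for
  the k qualifying proteins among the n subset members, exact via the
  binomial survival function (verified against full pmf summation for
  all n ≤ 12). One-sided because the scientific claim is "more regulated
  than the proteome at large". A degenerate p₀ ∈ {0, 1} (nothing or
  everything regulated) makes the test undefined; the pipeline then
  skips it with a logged note instead of fabricating a p-value.
* **Fisher over-representation**: per gene set, the one-sided
  (enrichment) Fisher exact p on the 2×2 table of study/background ×
  in-set/out-of-set, with gene sets intersected with the background
  first and study ⊆ background enforced. P-values are reported raw —
  the conventional screening criterion here is an unadjusted p ≤ 0.1 —
  with a BH-adjusted column alongside for transparency. Annotation
  content (pathway databases) is a user-supplied table, not downloaded.
* **Cohen's d**: pooled-SD standardized mean difference; undefined
  (NaN, flagged) when the pooled SD is zero.

## Image quantification

Masks are inputs (a fixed-threshold builder is included; automatic
thresholding pipelines are intentionally not reproduced). The three
measures: mean in-mask intensity; collagen coverage of myelin as
100·|mask_col ∧ mask_mbp|/|mask_col| (denominator switchable to
|mask_mbp|); and overlap intensity normalized first by the coverage
percentage, then by |mask_mbp|, in that fixed order. Units of the third
measure are arbitrary — only ratios between groups are meaningful. All
measures depend on mask membership only, not pixel positions
(permutation-invariance is tested).

## Synthetic-data generator

The generator emulates the *structure* of peripheral-myelin LFQ data,
not any particular deposited dataset:

* **Abundance**: log-normal across proteins (log₂ mean 20, sd 2 —
  typical iBAQ orders of magnitude and dynamic range), with the first
  three proteins pinned so their expected shares equal `top_fractions`
  (default 40/17/6 %, the dominance regime of MPZ/MBP/PRX in young
  myelin). Pinned proteins never carry differential effects, mirroring
  the stability of the major myelin proteins.
* **Within-group noise**: multiplicative log-normal with mean 1 and
  CV 0.25. Within-group CVs of the real pools are not published;
  0.25 is a realistic LFQ figure and is a documented default, not an
  estimate of the real data.
* **Differential effects**: a `de_fraction` subset (default 5 %)
  receives log₂FC with magnitude |N(2, 1)| and random sign (aging), or
  negative sign (injury downregulation).
* **Dropout**: MNAR first — per-cell Bernoulli with probability
  `expit(steepness·(midpoint − log₂ intensity))` (defaults: midpoint 17,
  steepness 1, i.e. censoring becomes likely ~1.5 decades below the
  typical protein) — then MAR uniformly at rate 0.02 on surviving
  cells. Applying MNAR before MAR makes the two truth labels exhaustive
  and exclusive. Setting `mnar_midpoint = -inf` disables censoring.
* **Injury design**: one intact and one crushed sample per mouse; the
  first `n_myelin` proteins (default one fifth of the proteome,
  including the pinned dominant ones) form the designated myelin set,
  of which a `down_fraction` carries negative effects, as does a
  configurable background fraction elsewhere.
* **Determinism**: one `numpy` generator stream per simulation seed;
  identical config + seed reproduces bit-identical matrices, truth and
  mechanism labels.

What the generator does **not** emulate: peptide-level structure and
shared peptides, correlated protein modules, batch and loading effects,
non-multiplicative error at the low-intensity end, or contaminants.
Passing tests therefore demonstrate correctness and calibration of the
*statistical machinery* under a realistic abundance/missingness
structure — not that any specific biological dataset would yield
specific numbers.

## Verification and problem sizes

The test suite checks every exactly-computable statistic against an
independent oracle (binomial tail vs pmf summation for all n ≤ 12;
Fisher p vs exact hypergeometric enumeration for all 2×2 tables with
total ≤ 12; Spearman ρ vs a first-principles mid-rank oracle on 500
tied vectors; the tryptic digest vs a regex position-scan oracle over
all ~87,000 sequences of length ≤ 8 on {A, K, R, P} and vs
pyteomics). Calibration checks use 5,000-protein null and 10 %-effect
simulations (10 and 20 seeds), prior recovery uses 5,000 proteins from
a known scaled inverse-χ² prior (d₀ = 4, s₀² = 0.05, 10 seeds), the
end-to-end null pipeline uses 600-protein generators over 10 seeds, and
the injury binomial power/null checks use 300/240-protein generators
over 10/100 seeds. These sizes were chosen so the whole suite completes
in well under a minute while keeping Monte-Carlo error comfortably
inside the asserted tolerances.

## Known limitations

* The local-FDR criterion used by some upstream analyses is not
  implemented; q < 0.05 (BH/Storey) is the shipped criterion.
* The knn imputer is O(targets × proteins) per comparison — fine for
  proteome-scale tables (thousands of rows), not tuned for much larger
  matrices.
* The Spearman p-value uses the t approximation; exact permutation is
  only feasible (and only used, as a test oracle) at very small n.
* Accession normalization strips isoform suffixes; species prefixes or
  gene-symbol mapping require a user-supplied mapping.
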