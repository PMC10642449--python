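# myelinlfq

A label-free quantitative (LFQ) proteomics analysis pipeline for
peripheral-nerve myelin, built around the comparisons that matter in
that system: an unpaired young-versus-old myelin-fraction comparison
(n = 3 nerve pools per age group) and a paired intact-versus-crushed
sciatic-nerve comparison (one nerve pair per mouse, sampled at several
days post crush). It is aimed at proteomics analysts who receive
protein-group intensity tables (MaxQuant/Spectronaut style) and want a
tested, scriptable route from raw intensities to differential-abundance
calls, enrichment statistics and fluorescence-section quantification —
plus a synthetic-data generator that reproduces the structure of this
kind of data so every stage can be validated with known ground truth.

## What it computes

**iBAQ quantification.** For protein *i*, iBAQ_i = (Σ peptide
intensities) / N_i, where N_i is the number of theoretically observable
fully-tryptic peptides (cleavage after K/R unless followed by P; length
window 7–30 by default). Relative abundance is reported as
100·iBAQ_i/Σ_j iBAQ_j. In peripheral myelin the three dominant proteins
(MPZ, MBP, PRX) jointly account for roughly 60–75 % of total signal,
and the generator pins its top proteins to exactly that regime.

**Missingness-aware imputation.** For each two-group comparison every
protein row is classified from its replicate presence pattern:
*MNAR* (missing not at random: heavily missing in one group, fully
observed in the other — treated as a real depletion and imputed with
MinDet, i.e. each missing cell gets the minimum observed value of its
sample column), *MAR* (at most one missing per group at n = 3 — imputed
by k-nearest-neighbour rows, k = 10), or *filtered* (fewer than two
observed values in both groups, or any other uninformative pattern).
Every imputed cell is written to an audit table.

**Moderated differential testing.** After quantile normalization, each
protein's pooled variance s² is shrunk toward a prior s₀² with prior
degrees of freedom d₀ estimated across the proteome (moment-matching on
log s²; checked against Bioconductor limma to 1e-10):

    s²_post = (d₀·s₀² + df·s²) / (d₀ + df),
    t_mod   = log₂FC / sqrt(s²_post·(1/n₁ + 1/n₂)),   df_total = df + d₀.

The paired injury comparison uses a paired t-test on within-pair log₂
differences. Multiple testing is corrected with Benjamini–Hochberg or
Storey q-values.

**Enrichment.** A one-sided binomial test asks whether a protein subset
(e.g. the myelin proteins) is downregulated more often than the
proteome-wide "ground probability" p₀ = fraction of all quantified
proteins with log₂FC < 0 and q < 0.05; Fisher-exact over-representation
runs against the quantified proteome as background. Cohen's d is the
pooled-SD standardized mean difference.

**Image quantification.** Three mask-based measures for two-channel
(collagen/myelin) fluorescence sections: in-mask mean intensity
(integrated density / area), collagen coverage of the myelin mask (%),
and overlap intensity normalized by coverage and myelin area, with an
unpaired t-test + Cohen's d group comparison.

## Worked example

```python
from myelinlfq import SimulationConfig, simulate_lfq_experiment, run_aging_pipeline
from myelinlfq.synthetic_data import default_aging_design

cfg = SimulationConfig(n_proteins=500, de_fraction=0.05, seed=42)
matrix, truth = simulate_lfq_experiment(cfg)     # raw intensities, NaN = missing
report = run_aging_pipeline(matrix, default_aging_design(cfg))

print(report["stage_log"].to_string(index=False))
de = report["de"]
print("DEPs (q < 0.05):", int((de["q"] < 0.05).sum()), "of", len(de))
print("top-3 combined share (young): %.1f%%" % report["shares"]["young"].iloc[:3].sum())
```

prints

```
             stage  proteins_in  proteins_out                note
  detection_filter          500           477      min_detected=2
    log2_transform          477           477
        imputation          477           444   imputed_cells=227
quantile_normalize          444           444
  moderated_t_test          444           444 d0=5.75 s0_sq=0.109
               fdr          444           444  method=bh pi0=None
   fc_vs_abundance          444           444    rho=-0.211 n=441
DEPs (q < 0.05): 13 of 444
top-3 combined share (young): 60.9%
```

Reading this: 23 of 500 simulated proteins fail the detection filter
(fewer than 2 of 3 observed values in every group); 33 more are dropped
as uninformative while 227 missing cells are imputed (MinDet or knn,
itemized in `report["audit"]`); variance shrinkage is fitted at
d₀ ≈ 5.8 extra degrees of freedom; 13 proteins are called differentially
abundant at q < 0.05 (the generator planted ~5 % true effects); and the
three pinned dominant proteins jointly carry ~61 % of total signal, in
the expected dominance window.

The same analyses are available from the shell:

```
myelinlfq simulate lfq --seed 1 --out sim/
myelinlfq run-aging --matrix sim/intensity_matrix.tsv --design sim/design.tsv --out report/
myelinlfq simulate injury --seed 2 --out inj/
myelinlfq enrich binomial --de-table report/de_results.tsv --subset myelin.txt --out binom.tsv
```

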