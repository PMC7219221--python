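# Methods

## Expression normalization

Raw quantification values (RSEM/RPKM scale) are processed per the TCGA PCPG
convention: each sample is scaled so the upper quartile of its positive
values equals `uq_target` (default 1000), values are transformed with
`log2(x + 1)`, and each gene is centered by its median across samples.
The pseudocount keeps zeros finite; any per-sample positive rescaling of
the input is absorbed by the upper-quartile step, which is tested as an
invariance property. Genes with zero counts in every sample are removed
from foreign-species matrices before normalization (reference matrices are
assumed pre-filtered). Median centering is applied **before** gene
selection; the run manifest records this order.

A sample whose values are all zero has no defined upper quartile and is
rejected by name rather than silently scaled.

## Variable-gene selection

Genes are ranked by scaled median absolute deviation
(`median |x − median(x)| × 1.4826`) and the top `mad_top_n` (default 3000)
kept. The 1.4826 consistency constant is cosmetic for ranking; ties are
broken lexicographically by gene id so the panel is reproducible.

## Consensus clustering

For each of `n_resamples` iterations (default 1000; 100 in the acceptance
runs, which is already saturating on these cohorts), `ceil(0.8 n)` samples
are drawn without replacement and partitioned into `k` groups by
agglomerative clustering — 1 − Pearson correlation distance with average
linkage by default; Euclidean distance and complete/Ward linkage are
configurable. All genes are retained in every draw (no feature
subsampling). The consensus matrix is the ratio of co-clustering to
co-sampling counts per sample pair; pairs never drawn together (vanishing
probability at the defaults) get consensus 0 with a logged warning. Final
labels cut an average-linkage tree built on `1 − consensus`. A
zero-variance sample makes correlation distance undefined and is rejected
by name.

Model selection across `k` uses the area under the empirical CDF of
off-diagonal consensus values. For an empirical CDF on [0, 1] this area
equals `1 − mean(values)` exactly, which is how it is computed (no
histogram approximation). The selected `k` is the largest whose relative
area gain over `k − 1` exceeds 0.05, falling back to the `k` with the
largest gain.

One seeded NumPy generator, consumed in iteration order, makes every fit
bit-reproducible; the seed is stored in the results object.

## Cross-species projection

The reference cohort is clustered alone to give the baseline subtype
solution. Each foreign sample is then inserted **individually**: the
combined raw matrix is re-normalized (so the insert participates in the
same upper-quartile/log2/median-centering transform), consensus clustering
is re-run at the baseline `k` (never re-selected with foreign samples
present), joint clusters are matched one-to-one onto baseline clusters by
Hungarian assignment over the reference samples, and the foreign sample
inherits its joint cluster's matched name. A joint cluster containing no
reference samples is "novel"; the foreign sample then falls back to the
baseline cluster with the highest mean consensus, and the per-cluster mean
consensus values are always reported as diagnostics.

The joint mode (all foreign samples at once) exists to demonstrate why the
one-at-a-time design is necessary: a shared species effect makes foreign
samples mutually similar, so jointly they capture their own cluster. The
package treats this as a first-class, tested behavior — mean
foreign–foreign consensus exceeding every foreign-to-reference consensus
at large offsets, and the effect vanishing (in expectation over seeds) as
the offset shrinks.

## Arm-level copy-number events and synteny

SEG input is read as 1-based inclusive (UCSC text convention) and held
0-based half-open internally; `chr` prefixes are stripped so `chr5` and
`5` match. Per arm, the loss fraction is the summed length of
`segment ∩ arm` over segments with copy number `< loss_cn_cutoff`
(default 2, diploid baseline) divided by the full arm length — uncovered
territory counts as neutral, since the event rule is phrased as a fraction
of the arm. An arm event is called only when the fraction **strictly**
exceeds `arm_loss_threshold` (default 0.5): a fraction of exactly one half
is neutral. Cohort frequencies are the per-arm proportion of samples
called. Arm coordinates come from UCSC cytoBand files, aggregated by the
leading p/q letter of the band name.

Syntenic proportion between a rat arm and a human chromosome is the count
of high-confidence one-to-one ortholog pairs linking them divided by that
human chromosome's total gene count. The concordance table joins these
proportions (restricted to the rat arms lost in the model) to human cohort
arm-loss frequencies — the human side may be a chromosome or an arm — and
reports a Spearman rank correlation (undefined with a warning on a
single-row join). Arm-significance machinery (GISTIC q-values) is out of
scope; only the explicit >50% rule is implemented.

## Ortholog handling

Only `one2one` + high-confidence homology records are used, and a
uniqueness sweep additionally drops any rat or human gene appearing in
more than one surviving record (one pass suffices; the operation is
idempotent). Non-one-to-one orthologs are discarded entirely rather than
aggregated across paralogs; drop counts are reported. Gene identifiers are
opaque case-sensitive strings; no symbol/ID conversion is attempted.

## Exact statistics

The two-sided Fisher exact p sums hypergeometric probabilities (fixed
margins) of all tables no more likely than the observed one, with a 1e-7
relative tolerance on the probability comparison (as in R). Degenerate
margins give p = 1 with a warning. The implementation is checked against
an independent library oracle over exhaustive small tables and random
tables up to total 100.

Fold ratios are rounded half-to-even at two decimals (raw ratios are also
emitted); a zero reference value yields an explicit undefined flag, never
infinity. Four cells of the built-in HIF2a marker table are flagged
because their printed ratios cannot be recomputed from their own printed
inputs (`pcpgx.datasets.MARKER_RATIO_DISCREPANCIES`); the package reports
the recomputed values. Metabolite ties share the smaller rank and sort
alphabetically within the tie. Ensemble variant voting accepts keys
present in ≥ `min_callers` call sets (default 2 of 3) and is monotone in
the threshold.

## Synthetic data

The generator emulates the study conditions, not any specific dataset:

* **Reference cohort** — 173 samples in four subtypes (60/50/40/23;
  pseudohypoxia, kinase, WNT-altered, cortical-admixture naming). Centroids
  live on the log2 scale: a shared Uniform(3, 8) baseline, an exclusive
  block of 20 marker genes per subtype, and a family block of 20 genes
  shared by consecutive subtype pairs at 0.7× the marker elevation —
  related subtypes correlate positively, as real tumor subtypes do.
  Elevations are scaled so the **minimum** pairwise centroid distance
  equals `separation × noise_sd` (default 10σ); cross-family pairs sit
  farther. Marker and family genes carry noise SD `noise_sd` (default 1);
  background genes 0.1× that — subtype markers being the high-variance
  genes is exactly what makes MAD selection meaningful. Raw values are
  `2**(centroid + noise) − 1`, truncated at 0.
* **Foreign samples** — target-subtype centroid plus a single shared
  offset of norm `species_offset_scale × separation × noise_sd` in a
  random direction over background genes (a species-specific program
  orthogonal to every human subtype program), plus per-sample noise.
* **Homology** — exactly `round(mappable_fraction × n_genes)` genes
  (default 1699/3000) receive unique one2one high-confidence partners; the
  remainder become one2many/many2many/low-confidence decoys that cannot
  survive restriction. Genes are placed uniformly on toy rat arms and
  human chromosomes; a cytoBand file is emitted.
* **SEG cohorts** — per arm, a prescribed loss probability; a drawn loss
  covers a strictly-greater-than-half fraction of the arm at copy number
  1 (integer lengths are bumped when flooring would land exactly on one
  half), the rest at 2. Truth tables record every intended call.

All generation is a pure function of (spec, seed), and every artifact
validates under the corresponding reader.

### Design rationale and what the simulations do not show

The gene-space geometry is the one genuinely open design choice. Uniform
unit noise across thousands of genes makes an 8–10σ centroid separation
unrecoverable by pairwise-distance clustering (the separation disappears
into the bulk noise), and with mutually orthogonal subtype blocks a
distant foreign blob can never become more anti-correlated with the
reference than weakly related subtypes are with each other, so the
joint-mode species artifact would never occur. Both features of real
data — low-variance background genes and positively correlated related
subtypes — are therefore built into the generator, with the family
strength (0.7) chosen so that reference clustering, one-at-a-time
projection and the joint artifact all behave as in the study.

The simulations establish *mechanism correctness* (the pipeline recovers
known structure under a faithful noise model), not performance on real
cohorts: real tumors have correlated gene-gene noise, batch effects beyond
a single shared offset vector, continuous rather than discrete subtype
boundaries, and species differences that touch marker genes. Passing
tests therefore do not certify recovery rates on real TCGA-scale data.

## Problem sizes and tolerances

Acceptance-scale runs use the study conditions (173 reference samples,
3000 genes, 1699-gene panel) at 100 consensus resamples, 20 replicate
offsets for projection accuracy, and 20-sample SEG cohorts; the unit suite
uses reduced cohorts (≤ 600 genes, ≤ 50 samples) for speed. Numeric
comparisons use exact equality for counting/deterministic quantities,
1e-9 for normalization medians, and printed precision (2–7 decimals) for
the reproduced table statistics. The exhaustive Fisher oracle covers all
tables with total ≤ 16 plus hundreds of random tables up to total 100.

## Known limitations

* No GISTIC significance model; arm-loss frequencies are raw proportions.
* Paralog expression is dropped, not aggregated, during ortholog mapping.
* `ward` linkage on a precomputed correlation distance is permitted but
  geometrically heterodox; the default is average linkage.
* The projection's fixed-`k` assumption means a genuinely novel foreign
  subtype is only detectable through the "novel"/low-consensus
  diagnostics, not as an extra cluster.
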