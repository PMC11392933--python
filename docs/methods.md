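# Methods

This note documents the models and procedures implemented in `mga`, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions a maintainer would want
written down.

## Candidate causal variant (CCV) selection

For each genome-wide-significant locus the selection keeps the lead variant,
any conditional-signal leads, and every variant satisfying either of two
rules relative to the lead:

- **Likelihood ratio.** Under the normal approximation to the association
  statistic, the likelihood ratio between variant *v* and the lead is
  `exp((z_v² − z_lead²)/2)`. A variant is kept when this ratio is at least
  1:1000, i.e. `z_lead² − z_v² < 2 ln 1000 ≈ 13.8155`. When only a two-sided
  p-value is available, `|z| = Φ⁻¹(1 − p/2)`.
- **LD.** `r²` to the lead at least 0.8. The boundary is inclusive by
  default and exposed as `r2_inclusive`, since ≥ and > both circulate for
  this rule in practice.

Each variant is reported once with the strongest applicable reason
(lead > conditional > llr > ld). Merging across studies deduplicates on
(chrom, pos, ref, alt) and retains every locus membership on one record;
conflicting alleles under one rsID are an error, not a silent overwrite.
No formal Bayesian fine-mapping is attempted.

## cCRE atlas

**Detection.** MACS2-style per-cell-type peak calling is out of scope; peak
*j* is "detected" in type *t* when at least `max(min_cells, min_frac·n_t)`
cells of the type have a nonzero count (defaults 10 cells / 2%). These
defaults recover the generator's planted patterns essentially exactly when
leak-through accessibility is zero and at ≥95% accuracy at the default
noise level.

**Genomic context.** Promoter (peak overlaps TSS ± 3000 bp, symmetric for
both strands) > exonic > intronic > intergenic. Gene activity is the summed
accessibility over the window from 2000 bp upstream of the TSS
(strand-aware) through the TES; a zero-width gene body degrades to the
promoter window with a warning.

**Specificity.** A peak detected in exactly one cell type is cell-type
specific. Category specificity follows the quantile rule: if all detecting
types share one category, that category; otherwise every category *g* whose
detected count satisfies `c_g > 0.75·n_g` (strict). For category sizes
(8, 7, 4, 4) the strict thresholds are (6, 5.25, 3, 3), so the counts
required are 7, 6, 4, 4. The 25th percentile is *not* used for assignment —
only the upper quantile has an unambiguous worked interpretation — but a
`category_depletion` annotation (counts strictly below `0.25·n_g`) is
provided for completeness.

## Allelic TF binding

A motif window scores `Σ_pos ic_pos · P(base, pos)`, min–max normalized by
the motif's worst/best attainable windows so consensus = 1 and
anti-consensus = 0 (information-content weighting of the PWM
probabilities). The motif-match p-value is the probability a random
background window scores at least as high: exact by enumeration of the
per-position score distribution for widths ≤ 10, seeded Monte Carlo
(10⁵ draws) otherwise.

For a variant, only motif placements **covering the variant** are compared
between the reference and alternate haplotypes (the convention of
motif-disruption tools; scoring the whole ±30 bp window on both alleles
would let an unrelated flanking pseudo-site mask the local disruption).
A variant is called allelic when `|alt_score − ref_score| > 0.7` and the
better allele is a credible match (`p ≤ 1e-4`; a printed threshold of
"10^4" for a p-value is read as 10⁻⁴ since p cannot exceed 1). Both
thresholds are configurable.

Note an intrinsic property of this scoring: a single-base substitution can
move the normalized score by more than 0.7 only when one motif position
carries the majority of the total information content. The generator's
planted motifs are built accordingly (below).

**Abundant TF.** A (TF, cell type) pair is abundant when the TF is
expressed in >50% of the type's cells and its mean log-normalized
expression (ln(1 + CP10K), mean over all cells of the type) exceeds the
75th percentile — linear-interpolation quantile — of mean expression over
all predicted TF–type pairs. Mean-over-all-cells was chosen over
mean-over-expressing-cells as the less biased statistic at high dropout.

## TF footprinting

Per (TF, cell type): Tn5 insertions (both fragment ends) are aggregated in
a ±250 bp window around motif occurrences inside peaks detected in that
type, normalized to mean 1 over the outer flank (|d| ∈ [200, 250]). The
expected profile is the positional bias model aggregated at the same
offsets under the same normalization (flat when no bias model is supplied),
and `corrected = observed − expected`. Detection replaces the visual call
used in practice with an explicit rule: flank enrichment
(mean corrected, 20 ≤ |d| ≤ 100) ≥ 0.05 **and** center depletion
(mean corrected, |d| ≤ 10) ≤ flank·(1 − 0.2). Fewer than 20 occurrences, or
an empty outer flank, yields an insufficient-data profile that is never
detected. On bias-only synthetic fragments the false-detection rate of the
best-powered profile is ≤5% at these defaults; at protection factor 0.2 the
planted bound cell types are detected and rank first by flank enrichment.

## Trait relevance scores (TRS)

Each locus contributes total mass 1 split evenly across its CCVs; a peak's
trait weight sums the masses of CCVs inside it. A cell's observed score is
`Σ_j w_j x_cj` divided by the cell's total accessible counts. The null
replaces every weighted peak with one of its 50 nearest matched peaks
(GC fraction when a genome is available, mean accessibility, width; z-space
nearest neighbors), 50 background sets by default, and the raw score is the
per-cell z against that null.

Propagation: seeds are the top 5% of cells by raw z (ties broken by cell
id); on the mutual kNN graph (k = 30 by default) of the TF-IDF/truncated-SVD
embedding (30 components, first dropped as depth-correlated), TRS is the
stationary distribution of a restart random walk (restart 0.05, uniform
restart over seeds), iterated to ‖Δ‖∞ < 1e-6 and rescaled to mean 1.
Restart = 1 returns the normalized seed indicator exactly, and the iterate
matches a direct linear solve to 1e-6 on small graphs. Cells outside the
largest connected component are flagged and assigned the component-TRS
quantile matching their raw-z rank — a deliberate, documented fallback
rather than a propagated value. The propagation hyperparameters beyond the
5% seed fraction are not externally specified; all are config-surfaced.

## Co-accessibility, modules, and peak–gene links

Cells are grouped into metacells — disjoint groups of k nearest neighbors
(default 50; `floor(n/k)` metacells, remainder cells unassigned) in the
same TF-IDF/SVD embedding — and counts summed, densifying the near-binary
accessibility. Co-accessibility of two peaks within 500 kb is the Pearson
correlation of their metacell counts; this deliberately replaces the
distance-penalized graphical-lasso estimator of the original tooling with a
dependency-free score honoring the same contract (symmetric, bounded,
distance-limited), with the same working cutoffs: ≥0.32 for module edges
(Louvain communities of ≥2 peaks, seeded for determinism, ties resolved by
lowest peak coordinate) and ≥0.5 for "directly co-accessible" pairs.

Peak–gene links correlate unit-level (metacell or cell) accessibility and
expression for peaks within ±1 Mb of the TSS (±2/±5 Mb variants provided).
Each focal peak is matched to its 200 nearest peaks in standardized
(GC, mean accessibility, width) space — the three bias covariates named for
this correction; the matching mechanism itself is this package's choice —
and the focal correlation is standardized against the background
correlations with the same gene: `z = (r − mean_null)/sd_null`,
`p = one-sided normal tail` (two-sided by flag). A link is retained when
`p < 0.05`, the focal `r` also exceeds the same quantile of its matched
background correlations (empirical rank p < 0.05), and `|r| > 0.05`. The
rank condition exists because the normal-tail z test alone is measurably
anticonservative (~5.5% empirical null rate) at desk-scale unit counts,
where Pearson correlations over ~70 metacells have heavier-than-normal
tails; the rank test is exactly calibrated under exchangeability and leaves
planted-link sensitivity unchanged (measured: null retained rate 4.4%,
sensitivity 0.99).

The background pool is genome-wide, not window-restricted, so a
(peak, gene) pair receives identical (r, z, p) at every window width and
the retained sets nest exactly across ±1/±2/±5 Mb.

**Levels.** For each CCV-colocalizing cCRE all six predicates are
evaluated: (1) a module mate is a promoter cCRE; (2) a directly
co-accessible peak is a promoter cCRE; (3) the cCRE is itself a promoter;
(4) a module mate has a retained gene link; (5) a directly co-accessible
peak has a retained gene link; (6) the cCRE itself has a retained link.
One record per (cCRE, gene) carries the maximum level and the full evidence
chain; a cCRE linked to several genes yields several records, none
filtered.

## Variant functional score

Only colocalized CCVs are scored (minimum 1):
`score = [cCRE overlap] + [≥1 allelic TF] + [abundance match] +
[footprint match]`. The abundance indicator requires the abundant cell type
to be among the types detecting an overlapping cCRE; the footprint
indicator is type-agnostic. Both requirements are flags. The additive
reading is used throughout (a gated alternative would only relabel
score-3 records).

## The synthetic generator

The generator is the package's test bed, not a data simulator of record.
It emulates: 23 cell types in four unbalanced categories (8/7/4/4, default
180 cells per type); Bernoulli presence/absence accessibility with
per-cell depth (lognormal, σ=0.25, clipped so probabilities stay ≤1),
open probability 0.8 in a peak's planted pattern types and 0.02 elsewhere;
pattern mix 35% single-type / 40% single-category / 25% shared, mirroring
the strong cell-type specificity of real cCRE atlases; negative-binomial
expression (base mean 2, dispersion 2) with per-cell-type markers (one per
type, 6× elevation, promoter-domain peaks sharing the marker's pattern)
and planted enhancer→gene effects that multiply the NB mean by 3 in cells
where the enhancer is open; AR(1) LD (ρ=0.95) with one causal variant per
locus at non-centrality 7, the lead chosen as max |z| and `r²_to_lead`
taken from the correlation closed form; planted motifs with a dominant-
information anchor position (consensus A at 0.97; other positions C/G at
0.45) so a single anchor substitution is a >0.7 allelic disruption, with
C/G-only planted flanks preventing spurious anchor alignments on either
strand; and fragment-level insertions sampled from a smooth sinusoidal
positional bias (amplitude 0.15, period 190 bp) with footprint protection
(factor 0.2 over the central ±10 bp) and flank enrichment whose amplitude
scales with (1 − protection), so "no protection" means a flat profile.

Two genome layouts serve different questions. The default **dense** layout
packs peaks every ~2 kb on a few compact chromosomes — suitable for the
atlas, TRS, TF, and end-to-end stages, and small enough that the genome
sequence can be synthesized. The **islands** layout places one gene, its
planted enhancers (two by default, sharing one accessibility pattern so
coinherited regulatory peaks form co-accessibility modules), and a few
unlinked peaks per island, with islands separated by more than twice the
widest cis window. This is the geometry used for link calibration and
recovery: at any realistic scaled-down peak density every ±1 Mb window
contains hundreds of null candidate pairs, and no method retaining links at
p < 0.05 could keep false links below 10% of retained — island sparsity
makes planted-link recovery a well-posed desk-scale question.

Not emulated: doublets, batch effects, ambient RNA, read-level sequence
errors, genotype-level LD (correlated z-scores are drawn directly from the
AR(1) model), trans effects, and distance-decaying co-accessibility.
Passing tests therefore demonstrate the correctness and calibration of the
pipeline's logic under its stated model, not robustness to the artifacts of
real droplet multiome data.

Determinism: every stage draws from its own child generator spawned from
the config seed, so a stage's output is identical whether or not other
stages run, and the full pipeline is byte-reproducible.

Fragments are emitted only for peaks carrying planted motif occurrences by
default (`fragment_peaks="motif"`); footprinting is the only consumer, and
emitting all ~10⁶⁺ open-entry fragments at the default scale would serve no
stage.

## Problem sizes used by the validation suite

The automated checks run at reduced, fixed sizes chosen to keep each
experiment's statistics well-powered: quantile-rule oracle on 10,000 random
rows; CCV oracle on 100 loci × 30 variants; linkage-level oracle on 200
random instances of 25 peaks × 5 genes; link calibration on 20 null seeds
(30 genes, 3 null peaks each, 24 cells/type) and recovery on 5 seeds with
60 planted links; footprint calibration on 100 seeds (40 sites, 24
cells/type) and recovery on 5; TRS recovery on 100 seeds (10 loci, 16
cells/type); determinism via two byte-compared pipeline runs.

## Known limitations

- Co-accessibility has no distance penalty, so very long-range pairs within
  the 500 kb window are treated the same as proximal ones.
- The normal-tail link p-value is reported as stated but is mildly
  anticonservative on its own; retention relies on the paired rank
  condition (above).
- The k-mer Tn5 bias model is a hook only; the provided bias models are
  positional.
- Metacell grouping is greedy and order-dependent (deterministically so);
  no optimality is claimed.
- `locus_summary` attributes linked genes to a locus through any of its
  colocalizing cCREs; with shared cCREs across loci, genes can be counted
  in several loci (unique counts are reported globally).
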