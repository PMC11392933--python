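# mga — multiome GWAS annotation

`mga` annotates GWAS risk loci with barcode-shared single-cell multiome
(snATAC-seq + snRNA-seq) data. It is aimed at statistical geneticists and
regulatory genomicists who have per-cell-type accessible-chromatin peaks
(cCREs) and matched expression for a tissue, and want to know — for each
associated locus — *which variants* are plausibly functional, *in which cell
types*, and *through which genes*.

The pipeline implements, as a reusable library with a CLI:

- **CCV selection.** A locus's candidate causal variants are its lead SNP,
  conditional-signal leads, and every variant with likelihood ratio within
  1:1000 of the lead (`z_lead² − z_var² < 2 ln 1000`, the normal asymptotic)
  or in strong LD with it (`r² ≥ 0.8`).
- **cCRE atlas.** Per-cell-type peak detection, promoter/exonic/intronic/
  intergenic annotation (TSS ± 3 kb), cell-type specificity (detected in
  exactly one type), and category specificity: with four cell categories
  (epithelial, immune, endothelial, stromal; 8/7/4/4 cell types), a peak
  detected across categories is attributed to category *g* iff its detected
  count `c_g` strictly exceeds the 75th percentile of the category size,
  `c_g > 0.75·n_g` (e.g. >6 of 8 epithelial types).
- **Colocalization + functional score.** A 1-based variant position *p*
  overlaps a half-open peak `[s, e)` iff `s < p ≤ e`. Colocalized CCVs get
  an additive 1–4 score: cCRE overlap + predicted allelic TF binding
  (|Δ relative score| > 0.7 with a motif-match p ≤ 1e-4) + cell-type-matched
  abundant TF (expressed in >50% of the type's cells, mean expression above
  the 75th percentile over predicted TF–type pairs) + detected TF footprint
  (bias-corrected Tn5 insertion dip with enriched motif flanks).
- **Trait relevance scores.** Per-locus probability mass split evenly over
  CCVs, summed per peak, correlated with per-cell accessibility against
  GC/accessibility/width-matched background peak sets, then propagated over
  a mutual-kNN cell graph by a restart random walk (5% seed cells).
- **Six-level cCRE→gene linkage.** Metacell co-accessibility (Pearson, 500 kb
  window; ≥0.32 module edges via Louvain, ≥0.5 "directly co-accessible") and
  background-corrected peak–gene expression links (±1/2/5 Mb, p < 0.05,
  |r| > 0.05) combine into the evidence hierarchy: (1) module mate is a
  promoter cCRE, (2) directly co-accessible with a promoter, (3) is itself a
  promoter, (4) module mate is gene-linked, (5) directly co-accessible with a
  gene-linked cCRE, (6) is itself gene-linked — level 6 strongest.

Because real multiome data is too large for development-scale testing, the
package ships a first-class synthetic generator (`mga.synthetic_data`) that
emulates the study design — 23 cell types in four unbalanced categories,
near-binary patterned accessibility, negative-binomial expression with
planted enhancer→gene effects, AR(1)-LD loci with one planted causal variant
each, motif-planted sequences with allelic variants, and fragment-level Tn5
insertions with planted footprints over a smooth bias field — and records
every planted truth for end-to-end validation.

## Worked example

Run the full pipeline on a small synthetic cohort (16 cells per type ×
23 types, 400 peaks, 80 genes, 3 loci × 15 variants):

```python
from mga.synthetic_data import SimConfig
from mga.variant_scoring import run_all

cfg = SimConfig(cells_per_type=16, n_peaks=400, n_genes=80, n_loci=3,
                variants_per_locus=15, n_links=10,
                footprint_sites_per_tf=25, seed=99)
results = run_all(cfg, out_dir="results/demo")
print(results["global_stats"])
```

which prints

```
{'n_loci': 3, 'n_unique_ccvs': 23, 'n_unique_colocalized': 7,
 'frac_loci_colocalized': 1.0, 'frac_loci_level6': 0.6666666666666666}
```

23 unique CCVs were selected across the 3 loci; 7 colocalized with a cCRE,
covering all 3 loci; 2 of 3 loci acquired at least one level-6 (directly
expression-linked) candidate gene. `results/demo/` then holds the full
evidence trail — `ccvs.tsv`, `atlas.tsv`, `colocalization.tsv`, `trs.tsv`,
`allelic_predictions.tsv`, `tf_abundance.tsv`, `footprints.tsv`,
`modules.tsv`, `peak_gene_links.tsv`, `linkage_records.tsv`,
`variant_scores.tsv`, `locus_summary.tsv` — plus `truth.json` (the planted
ground truth) and a `manifest.json` with the config hash. The per-locus
summary for this run:

```
locus_id  n_ccvs  n_colocalized  max_functional_score  n_linked_genes  n_level6_genes
    1_L1       7              2                     4              37               0
    2_L2      10              3                     3              26               8
    3_L3       6              2                     4              37               3
```

and the planted trait-relevant category (epithelial) attains the highest
mean trait relevance score (2.71 vs 1.88/1.84/0.02 for the other
categories; `trs_summary.tsv`).

The same stages are available from the shell:

```bash
mga simulate --config sim.yaml --seed 1 --out data/
mga select-ccvs --gwas data/gwas_stats.tsv --ld data/gwas_ld.tsv --out ccvs.tsv
mga atlas --bundle data/bundle --out atlas.tsv
mga run-all --seed 99 --out results/demo
```

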