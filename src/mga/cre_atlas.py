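"""Per-cell-type cCRE atlas: detection, genomic context, and specificity.

A peak is "detected" in a cell type when enough of that type's cells carry a
nonzero count. Specificity follows the quantile rule: a peak detected only
in one category belongs to that category; a peak detected across categories
is attributed to every category whose detected-type count strictly exceeds
75% of the category's size (e.g. >6 of 8 epithelial types). A peak detected
in exactly one cell type is additionally cell-type specific.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .types import (
    CategoryScheme,
    GeneModel,
    GenomicInterval,
    MultiomeBundle,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_FRAC = 0.02
DEFAULT_MIN_CELLS = 10
TSS_WINDOW = 3000
PROMOTER_UPSTREAM = 2000
QUANTILE_FRACTION = 0.75

CONTEXT_PRIORITY = ("promoter", "exonic", "intronic", "intergenic")


@dataclass
class PeakAtlas:
    """Peaks with per-cell-type detection flags and specificity labels."""

    peaks: list[GenomicInterval]
    cell_types: list[str]
    detection: np.ndarray  # peaks x cell_types, bool
    context: list[str]
    specific_cell_type: list[str | None]
    categories: list[frozenset[str]]
    scheme: CategoryScheme
    promoter_gene: list[tuple[str, ...]] = field(default_factory=list)
    source_indices: list[int] | None = None  # indices into the bundle peak list

    def __post_init__(self) -> None:
        self.detection = np.asarray(self.detection, dtype=bool)
        if self.detection.shape != (len(self.peaks), len(self.cell_types)):
            raise ValidationError("detection matrix shape mismatch")
        if not self.detection.any(axis=1).all():
            raise ValidationError("every atlas peak must be detected in >= 1 cell type")

    def detected_types(self, j: int) -> list[str]:
        return [t for t, d in zip(self.cell_types, self.detection[j]) if d]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, p in enumerate(self.peaks):
            rows.append(
                {
                    "chrom": p.chrom,
                    "start": p.start,
                    "end": p.end,
                    "context": self.context[j],
                    "detected_types": ";".join(self.detected_types(j)),
                    "specific_cell_type": self.specific_cell_type[j] or "",
                    "categories": ";".join(sorted(self.categories[j])),
                    "promoter_genes": ";".join(self.promoter_gene[j])
                    if self.promoter_gene
                    else "",
                }
            )
        return pd.DataFrame(rows)


def detect_peaks_per_type(
    bundle: MultiomeBundle,
    min_frac: float = DEFAULT_MIN_FRAC,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> tuple[np.ndarray, list[str]]:
    """Call peak detection per cell type from the cells x peaks count matrix.

    Peak j is detected in type t iff at least max(min_cells, min_frac * n_t)
    cells of type t have a nonzero count at j. Returns (peaks x types bool
    matrix, type order).
    """
    types = sorted(bundle.cell_meta["cell_type"].unique())
    X = bundle.atac.tocsc()
    nz = X.copy()
    nz.data = np.ones_like(nz.data)
    det = np.zeros((len(bundle.peaks), len(types)), dtype=bool)
    type_arr = bundle.cell_meta["cell_type"].to_numpy()
    for ti, t in enumerate(types):
        mask = type_arr == t
        n_t = int(mask.sum())
        if n_t == 0:
            logger.warning("cell type %s has 0 cells; excluded from detection", t)
            continue
        thresh = max(min_cells, min_frac * n_t)
        counts = np.asarray(nz[mask].sum(axis=0)).ravel()
        det[:, ti] = counts >= thresh
    return det, types


def annotate_genomic_context(
    peak: GenomicInterval,
    genes: list[GeneModel],
    tss_window: int = TSS_WINDOW,
) -> str:
    """Label a peak promoter/exonic/intronic/intergenic by priority.

    Promoter means overlapping TSS +/- tss_window (symmetric around the TSS
    for both strands); exonic/intronic require overlap with an exon or the
    gene body respectively. Highest-priority label wins.
    """
    label = "intergenic"
    rank = {c: i for i, c in enumerate(CONTEXT_PRIORITY)}
    for gene in genes:
        if gene.chrom != peak.chrom:
            continue
        prom = GenomicInterval(
            gene.chrom, max(0, gene.tss - 1 - tss_window), gene.tss + tss_window
        )
        if peak.overlaps(prom):
            return "promoter"
        if peak.overlaps(gene.span):
            if any(peak.overlaps(ex) for ex in gene.exons):
                cand = "exonic"
            else:
                cand = "intronic"
            if rank[cand] < rank[label]:
                label = cand
    return label


def promoter_genes_for_peak(
    peak: GenomicInterval, genes: list[GeneModel], tss_window: int = TSS_WINDOW
) -> tuple[str, ...]:
    """Gene ids whose TSS +/- window the peak overlaps (promoter assignment)."""
    out = []
    for gene in genes:
        if gene.chrom != peak.chrom:
            continue
        prom = GenomicInterval(
            gene.chrom, max(0, gene.tss - 1 - tss_window), gene.tss + tss_window
        )
        if peak.overlaps(prom):
            out.append(gene.gene_id)
    return tuple(sorted(out))


def cell_type_specificity(
    detection_row: np.ndarray, cell_types: list[str]
) -> str | None:
    """The single detecting cell type, or None when detection is shared."""
    row = np.asarray(detection_row, dtype=bool)
    idx = np.flatnonzero(row)
    if idx.size == 0:
        raise ValidationError("detection row has no detected cell type")
    if idx.size == 1:
        return cell_types[idx[0]]
    return None


def category_assignment(
    detection_row: np.ndarray,
    cell_types: list[str],
    scheme: CategoryScheme,
    quantile_fraction: float = QUANTILE_FRACTION,
) -> frozenset[str]:
    """Assign a detection pattern to cell-type categories by the 75% rule.

    If every detecting type lies in one category, that category is returned.
    Otherwise each category g with detected count c_g strictly exceeding
    quantile_fraction * n_g (n_g = category size) is returned; the empty set
    means "shared".
    """
    row = np.asarray(detection_row, dtype=bool)
    detected = [cell_types[i] for i in np.flatnonzero(row)]
    if not detected:
        raise ValidationError("detection row has no detected cell type")
    unknown = [t for t in detected if t not in scheme.mapping]
    if unknown:
        raise ValidationError(f"detection row references unknown cell type(s) {unknown}")
    cats = {scheme.mapping[t] for t in detected}
    if len(cats) == 1:
        return frozenset(cats)
    sizes = scheme.sizes
    counts: dict[str, int] = {}
    for t in detected:
        counts[scheme.mapping[t]] = counts.get(scheme.mapping[t], 0) + 1
    return frozenset(
        g for g, c in counts.items() if c > quantile_fraction * sizes[g]
    )


def category_depletion(
    detection_row: np.ndarray,
    cell_types: list[str],
    scheme: CategoryScheme,
    quantile_fraction: float = 0.25,
) -> frozenset[str]:
    """Optional annotation: categories whose detected count falls strictly
    below the 25th percentile of their size (depleted-in-category)."""
    row = np.asarray(detection_row, dtype=bool)
    detected = [cell_types[i] for i in np.flatnonzero(row)]
    sizes = scheme.sizes
    counts = {g: 0 for g in sizes}
    for t in detected:
        counts[scheme.mapping[t]] += 1
    return frozenset(g for g, c in counts.items() if c < quantile_fraction * sizes[g])


def gene_activity(
    bundle: MultiomeBundle,
    genes: list[GeneModel] | None = None,
    promoter_upstream: int = PROMOTER_UPSTREAM,
) -> np.ndarray:
    """Cells x genes activity from the peak matrix.

    Activity of gene g in cell c is the total accessibility count of peaks
    overlapping the window from promoter_upstream bp upstream of the TSS
    (strand-aware) through the TES.
    """
    genes = bundle.genes if genes is None else genes
    X = bundle.atac.tocsc()
    act = np.zeros((bundle.n_cells, len(genes)))
    by_chrom = _peaks_by_chrom(bundle.peaks)
    for gi, gene in enumerate(genes):
        win = _activity_window(gene, promoter_upstream)
        entry = by_chrom.get(win.chrom)
        if entry is None:
            continue
        idx, starts, ends = entry
        cols = idx[(starts < win.end) & (ends > win.start)]
        if cols.size:
            act[:, gi] = np.asarray(X[:, cols].sum(axis=1)).ravel()
    return act


def _peaks_by_chrom(
    peaks: list[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    out: dict[str, list[list[int]]] = {}
    for j, p in enumerate(peaks):
        out.setdefault(p.chrom, []).append(j)
    return {
        c: (
            np.asarray(js, dtype=int),
            np.asarray([peaks[j].start for j in js]),
            np.asarray([peaks[j].end for j in js]),
        )
        for c, js in out.items()
    }


def gene_activity_from_fragments(
    fragments, genes: list[GeneModel], cells: list[str],
    promoter_upstream: int = PROMOTER_UPSTREAM,
) -> np.ndarray:
    """Cells x genes activity from a fragment stream (interval, barcode, count)."""
    cell_idx = {c: i for i, c in enumerate(cells)}
    windows = [_activity_window(g, promoter_upstream) for g in genes]
    act = np.zeros((len(cells), len(genes)))
    for iv, bc, count in fragments:
        ci = cell_idx.get(bc)
        if ci is None:
            continue
        for gi, win in enumerate(windows):
            if iv.overlaps(win):
                act[ci, gi] += count
    return act


def _activity_window(gene: GeneModel, promoter_upstream: int) -> GenomicInterval:
    if gene.tss == gene.tes:
        logger.warning(
            "gene %s has zero-width body; using promoter-only window", gene.gene_id
        )
    if gene.strand == "+":
        start0 = max(0, gene.tss - 1 - promoter_upstream)
        end0 = max(gene.tes, gene.tss)
    else:
        start0 = max(0, min(gene.tes, gene.tss) - 1)
        end0 = gene.tss + promoter_upstream
    return GenomicInterval(gene.chrom, start0, max(end0, start0 + 1))


def _annotate_all(
    peaks: list[GenomicInterval], genes: list[GeneModel], tss_window: int
) -> tuple[list[str], list[tuple[str, ...]]]:
    """Vectorized context + promoter-gene annotation for a peak list."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    arrays = {}
    for chrom, gs in by_chrom.items():
        tss = np.asarray([g.tss for g in gs])
        span_s = np.asarray([g.span.start for g in gs])
        span_e = np.asarray([g.span.end for g in gs])
        arrays[chrom] = (gs, tss, span_s, span_e)
    context: list[str] = []
    promoter_gene: list[tuple[str, ...]] = []
    for p in peaks:
        entry = arrays.get(p.chrom)
        if entry is None:
            context.append("intergenic")
            promoter_gene.append(())
            continue
        gs, tss, span_s, span_e = entry
        prom = (np.maximum(0, tss - 1 - tss_window) < p.end) & (tss + tss_window > p.start)
        if prom.any():
            context.append("promoter")
            promoter_gene.append(
                tuple(sorted(gs[i].gene_id for i in np.flatnonzero(prom)))
            )
            continue
        promoter_gene.append(())
        body = (span_s < p.end) & (span_e > p.start)
        if body.any():
            label = "intronic"
            for i in np.flatnonzero(body):
                if any(p.overlaps(ex) for ex in gs[i].exons):
                    label = "exonic"
                    break
            context.append(label)
        else:
            context.append("intergenic")
    return context, promoter_gene


def build_atlas(
    bundle: MultiomeBundle,
    min_frac: float = DEFAULT_MIN_FRAC,
    min_cells: int = DEFAULT_MIN_CELLS,
    tss_window: int = TSS_WINDOW,
) -> PeakAtlas:
    """Run detection + context + specificity and keep peaks detected somewhere."""
    det, types = detect_peaks_per_type(bundle, min_frac=min_frac, min_cells=min_cells)
    scheme = CategoryScheme.from_bundle(bundle)
    keep = np.flatnonzero(det.any(axis=1))
    peaks = [bundle.peaks[j] for j in keep]
    det = det[keep]
    context, promoter_gene = _annotate_all(peaks, bundle.genes, tss_window)
    specific = [cell_type_specificity(det[j], types) for j in range(len(peaks))]
    cats = [category_assignment(det[j], types, scheme) for j in range(len(peaks))]
    return PeakAtlas(
        peaks=peaks,
        cell_types=types,
        detection=det,
        context=context,
        specific_cell_type=specific,
        categories=cats,
        scheme=scheme,
        promoter_gene=promoter_gene,
        source_indices=[int(j) for j in keep],
    )
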