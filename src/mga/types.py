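"""Core domain types shared across the pipeline.

Coordinate conventions: genomic intervals (peaks, fragments, exons) are
BED-style 0-based half-open; variant positions are VCF-style 1-based.
A variant at 1-based position ``p`` overlaps interval ``[s, e)`` iff
``s < p <= e``. Conversions happen only at parse/serialize boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

CATEGORIES = ("epithelial", "immune", "endothelial", "stromal")

_ALLELE_BASES = set("ACGT")


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


class FormatError(ValueError):
    """Raised when an external file cannot be parsed as its declared format."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"interval start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValidationError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_position(self, pos_1based: int) -> bool:
        """Whether a 1-based position falls inside this interval (s < p <= e)."""
        return self.start < pos_1based <= self.end

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Variant:
    """A sequence variant with a 1-based position and explicit alleles."""

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"variant pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"{self.variant_id}: ref and alt alleles are equal")
        for allele in (self.ref, self.alt):
            if not allele or not set(allele) <= _ALLELE_BASES:
                raise ValidationError(
                    f"{self.variant_id}: allele {allele!r} not over A/C/G/T"
                )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware TSS/TES.

    For '+' genes tss <= tes; for '-' genes tss >= tes (both 1-based).
    """

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.strand == "+" and self.tss > self.tes:
            raise ValidationError(f"{self.gene_id}: + strand requires tss <= tes")
        if self.strand == "-" and self.tss < self.tes:
            raise ValidationError(f"{self.gene_id}: - strand requires tss >= tes")
        lo, hi = min(self.tss, self.tes), max(self.tss, self.tes)
        for ex in self.exons:
            if ex.chrom != self.chrom or ex.start + 1 < lo or ex.end > hi:
                raise ValidationError(
                    f"{self.gene_id}: exon {ex} outside gene span [{lo}, {hi}]"
                )

    @property
    def span(self) -> GenomicInterval:
        lo, hi = min(self.tss, self.tes), max(self.tss, self.tes)
        return GenomicInterval(self.chrom, lo - 1, hi)


@dataclass
class MultiomeBundle:
    """Barcode-shared snATAC + snRNA matrices with per-cell metadata.

    ``atac`` is cells x peaks, ``rna`` is cells x genes, both sparse
    non-negative counts with rows aligned to ``cells``.
    """

    cells: list[str]
    peaks: list[GenomicInterval]
    genes: list[GeneModel]
    atac: sp.csr_matrix
    rna: sp.csr_matrix
    cell_meta: pd.DataFrame  # index: cell id; columns: sample_id, cell_type, category, smoking_status

    def __post_init__(self) -> None:
        n, p = self.atac.shape
        if n != len(self.cells) or p != len(self.peaks):
            raise ValidationError(
                f"atac matrix is {self.atac.shape}, expected "
                f"({len(self.cells)}, {len(self.peaks)})"
            )
        nr, g = self.rna.shape
        if nr != len(self.cells) or g != len(self.genes):
            raise ValidationError(
                f"rna matrix is {self.rna.shape}, expected "
                f"({len(self.cells)}, {len(self.genes)})"
            )
        if list(self.cell_meta.index) != list(self.cells):
            raise ValidationError("cell_meta index does not match cell id list")
        bad = set(self.cell_meta["category"].unique()) - set(CATEGORIES)
        if bad:
            raise ValidationError(f"unknown category label(s): {sorted(bad)}")
        # every cell type must map to exactly one category
        tc = self.cell_meta.groupby("cell_type")["category"].nunique()
        if (tc > 1).any():
            offenders = list(tc[tc > 1].index)
            raise ValidationError(
                f"cell type(s) mapped to multiple categories: {offenders}"
            )
        if (self.atac.data < 0).any() or (self.rna.data < 0).any():
            raise ValidationError("count matrices must be non-negative")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.cell_meta["cell_type"].unique())

    def type_to_category(self) -> dict[str, str]:
        return dict(
            self.cell_meta.drop_duplicates("cell_type")
            .set_index("cell_type")["category"]
        )


@dataclass
class CategoryScheme:
    """Mapping of cell types to the four lung cell categories."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        bad = set(self.mapping.values()) - set(CATEGORIES)
        if bad:
            raise ValidationError(f"unknown category label(s): {sorted(bad)}")

    @property
    def sizes(self) -> dict[str, int]:
        out = {c: 0 for c in CATEGORIES}
        for cat in self.mapping.values():
            out[cat] += 1
        return {c: n for c, n in out.items() if n > 0}

    @property
    def n_types(self) -> int:
        return len(self.mapping)

    @classmethod
    def from_bundle(cls, bundle: MultiomeBundle) -> "CategoryScheme":
        return cls(bundle.type_to_category())


@dataclass
class PWM:
    """A position weight matrix: 4 x L probabilities (rows A, C, G, T)."""

    name: str
    probs: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4:
            raise ValidationError(f"PWM {self.name}: probs must be 4 x L")
        colsums = self.probs.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise ValidationError(f"PWM {self.name}: columns must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def ic(self) -> np.ndarray:
        """Per-position information content in bits (relative to background)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = self.probs * np.log2(self.probs / self.background[:, None])
        terms = np.where(self.probs > 0, terms, 0.0)
        return np.clip(terms.sum(axis=0), 0.0, None)

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probs.argmax(axis=0))
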