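"""Readers and writers for every external format the pipeline touches.

Bundle directory layout (all plain text)::

    atac.mtx        MatrixMarket, cells x peaks counts
    rna.mtx         MatrixMarket, cells x genes counts
    barcodes.tsv    one cell barcode per line, row order of both matrices
    peaks.bed       BED3, column order of atac.mtx
    genes.tsv       gene_id, gene_name, chrom, strand, tss, tes (1-based)
    cell_meta.tsv   cell_id, sample_id, cell_type, category, smoking_status

Intervals are read and written 0-based half-open (BED); variants 1-based
(VCF-style). Fragment files are 5-column TSV (chrom, start, end, barcode,
count), coordinate-sorted, plain or gzipped.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import fields as dc_fields, is_dataclass, asdict
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .types import (
    FormatError,
    GeneModel,
    GenomicInterval,
    MultiomeBundle,
    PWM,
    ValidationError,
    Variant,
)

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 0.8


# ---------------------------------------------------------------------------
# multiome bundle


def load_multiome_bundle(matrix_dir: str | Path) -> MultiomeBundle:
    """Load a validated multiome bundle from a directory of MTX + TSV files."""
    d = Path(matrix_dir)
    barcodes = _read_lines(d / "barcodes.tsv")
    peaks = read_peaks_bed(d / "peaks.bed")
    genes = read_gene_models(d / "genes.tsv")

    atac = sp.csr_matrix(scipy.io.mmread(d / "atac.mtx"))
    rna = sp.csr_matrix(scipy.io.mmread(d / "rna.mtx"))
    if atac.shape[0] != len(barcodes):
        raise FormatError(
            f"atac.mtx declares {atac.shape[0]} rows but "
            f"{d / 'barcodes.tsv'} lists {len(barcodes)} barcodes"
        )
    if rna.shape[0] != len(barcodes):
        raise FormatError(
            f"rna.mtx declares {rna.shape[0]} rows but "
            f"{d / 'barcodes.tsv'} lists {len(barcodes)} barcodes"
        )
    if atac.shape[1] != len(peaks):
        raise FormatError(
            f"atac.mtx declares {atac.shape[1]} columns but "
            f"{d / 'peaks.bed'} lists {len(peaks)} peaks"
        )
    if rna.shape[1] != len(genes):
        raise FormatError(
            f"rna.mtx declares {rna.shape[1]} columns but "
            f"{d / 'genes.tsv'} lists {len(genes)} genes"
        )
    meta = pd.read_csv(d / "cell_meta.tsv", sep="\t", dtype=str).set_index("cell_id")
    if list(meta.index) != barcodes:
        raise FormatError(
            f"{d / 'cell_meta.tsv'} cell ids do not match {d / 'barcodes.tsv'}"
        )
    return MultiomeBundle(
        cells=barcodes, peaks=peaks, genes=genes, atac=atac, rna=rna, cell_meta=meta
    )


def write_multiome_bundle(bundle: MultiomeBundle, out_dir: str | Path) -> None:
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(d / "atac.mtx", sp.coo_matrix(bundle.atac))
    scipy.io.mmwrite(d / "rna.mtx", sp.coo_matrix(bundle.rna))
    (d / "barcodes.tsv").write_text("".join(c + "\n" for c in bundle.cells))
    write_peaks_bed(bundle.peaks, d / "peaks.bed")
    write_gene_models(bundle.genes, d / "genes.tsv")
    meta = bundle.cell_meta.reset_index()
    meta = meta.rename(columns={meta.columns[0]: "cell_id"})
    meta.to_csv(d / "cell_meta.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED / gene models


def read_peaks_bed(path: str | Path) -> list[GenomicInterval]:
    peaks = []
    for i, line in enumerate(_read_lines(path), start=1):
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{i}: BED line has fewer than 3 columns")
        try:
            peaks.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
        except (ValueError, ValidationError) as exc:
            raise FormatError(f"{path}:{i}: {exc}") from exc
    return peaks


def write_peaks_bed(peaks: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "gene_name", "chrom", "strand", "tss", "tes"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        GeneModel(
            gene_id=str(r.gene_id),
            gene_name=str(r.gene_name),
            chrom=str(r.chrom),
            strand=str(r.strand),
            tss=int(r.tss),
            tes=int(r.tes),
        )
        for r in df.itertuples()
    ]


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    rows = [
        (g.gene_id, g.gene_name, g.chrom, g.strand, g.tss, g.tes) for g in genes
    ]
    pd.DataFrame(
        rows, columns=["gene_id", "gene_name", "chrom", "strand", "tss", "tes"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# fragments


def load_fragments(
    fragments_path: str | Path,
    barcode_whitelist: set[str] | None = None,
    known_chroms: set[str] | None = None,
) -> Iterator[tuple[GenomicInterval, str, int]]:
    """Stream (interval, cell_id, count) records from a fragments file.

    Records with barcodes outside the whitelist are dropped. Records on
    chromosomes not in ``known_chroms`` (when given) are skipped with a
    warning rather than raising, so partial genomes can be used.
    """
    path = Path(fragments_path)
    opener = gzip.open if path.suffix == ".gz" else open
    warned_chroms: set[str] = set()
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise FormatError(
                    f"{path}:{lineno}: expected 5 tab-separated columns"
                )
            chrom, start_s, end_s, barcode, count_s = parts[:5]
            start, end, count = int(start_s), int(end_s), int(count_s)
            if end <= start:
                raise FormatError(
                    f"{path}:{lineno}: fragment end {end} <= start {start}"
                )
            if count < 1:
                raise FormatError(f"{path}:{lineno}: fragment count {count} < 1")
            if known_chroms is not None and chrom not in known_chroms:
                if chrom not in warned_chroms:
                    logger.warning("skipping fragments on unknown chrom %s", chrom)
                    warned_chroms.add(chrom)
                continue
            if barcode_whitelist is not None and barcode not in barcode_whitelist:
                continue
            yield GenomicInterval(chrom, start, end), barcode, count


def write_fragments(
    fragments: Iterable[tuple[GenomicInterval, str, int]], path: str | Path
) -> None:
    """Write fragments coordinate-sorted (chrom, start, end, barcode)."""
    recs = sorted(
        ((iv.chrom, iv.start, iv.end, bc, n) for iv, bc, n in fragments)
    )
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for chrom, start, end, bc, n in recs:
            fh.write(f"{chrom}\t{start}\t{end}\t{bc}\t{n}\n")


# ---------------------------------------------------------------------------
# motifs


def load_pwms(
    pwm_path: str | Path,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: np.ndarray | None = None,
) -> list[PWM]:
    """Load motifs from JASPAR or MEME text, column-normalized to probabilities.

    Counts ``c`` become ``(c + pseudocount * bg) / (colsum + pseudocount)``,
    the standard background-distributed pseudocount.
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    text = Path(pwm_path).read_text()
    if "letter-probability matrix" in text:
        raw = _parse_meme(text, pwm_path)
    else:
        raw = _parse_jaspar(text, pwm_path)
    pwms = []
    for name, counts in raw:
        colsums = counts.sum(axis=0)
        if (colsums <= 0).any():
            raise FormatError(
                f"{pwm_path}: motif {name} has a column not summing to a positive value"
            )
        probs = (counts + pseudocount * bg[:, None]) / (colsums + pseudocount)
        pwms.append(PWM(name=name, probs=probs, background=bg))
    return pwms


def _parse_jaspar(text: str, path) -> list[tuple[str, np.ndarray]]:
    motifs: list[tuple[str, np.ndarray]] = []
    name = None
    rows: dict[str, list[float]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                motifs.append((name, _assemble_jaspar_rows(rows, name, path)))
            name = line[1:].split()[-1] if len(line[1:].split()) > 1 else line[1:]
            rows = {}
        else:
            base = line[0].upper()
            if base not in "ACGT":
                raise FormatError(f"{path}: unexpected JASPAR row {line[:20]!r}")
            nums = line[1:].replace("[", " ").replace("]", " ").split()
            rows[base] = [float(x) for x in nums]
    if name is not None:
        motifs.append((name, _assemble_jaspar_rows(rows, name, path)))
    if not motifs:
        raise FormatError(f"{path}: no JASPAR motifs found")
    return motifs


def _assemble_jaspar_rows(rows, name, path) -> np.ndarray:
    if set(rows) != set("ACGT"):
        raise FormatError(f"{path}: motif {name} missing base row(s)")
    widths = {len(v) for v in rows.values()}
    if len(widths) != 1:
        raise FormatError(f"{path}: motif {name} has ragged rows")
    return np.array([rows[b] for b in "ACGT"], dtype=float)


def _parse_meme(text: str, path) -> list[tuple[str, np.ndarray]]:
    motifs: list[tuple[str, np.ndarray]] = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            name = line.split()[1]
            # advance to the letter-probability header
            while i < len(lines) and "letter-probability matrix" not in lines[i]:
                i += 1
            if i == len(lines):
                raise FormatError(f"{path}: motif {name} has no probability matrix")
            header = lines[i]
            width = None
            toks = header.split()
            if "w=" in toks:
                width = int(toks[toks.index("w=") + 1])
            i += 1
            cols = []
            while i < len(lines):
                row = lines[i].split()
                if len(row) != 4:
                    break
                cols.append([float(x) for x in row])
                i += 1
            mat = np.array(cols, dtype=float).T  # rows A C G T
            if width is not None and mat.shape[1] != width:
                raise FormatError(
                    f"{path}: motif {name} declares w={width} but has "
                    f"{mat.shape[1]} columns"
                )
            motifs.append((name, mat))
        else:
            i += 1
    if not motifs:
        raise FormatError(f"{path}: no MEME motifs found")
    return motifs


def write_pwms_jaspar(pwms: Iterable[PWM], path: str | Path, scale: int = 100) -> None:
    """Write motifs as JASPAR count matrices (probabilities x scale)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\n")
            for bi, base in enumerate("ACGT"):
                vals = " ".join(f"{v * scale:.2f}" for v in pwm.probs[bi])
                fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def load_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA into chrom -> uppercase sequence (desk-scale genomes)."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line.upper())
            elif line.strip():
                raise FormatError(f"{path}: sequence before first FASTA header")
    if not seqs:
        raise FormatError(f"{path}: no FASTA records")
    return {k: "".join(v) for k, v in seqs.items()}


# ---------------------------------------------------------------------------
# GWAS


def load_gwas_bundle(
    stats_path: str | Path, ld_path: str | Path
) -> dict[str, pd.DataFrame]:
    """Load per-locus GWAS variant tables joined to LD-to-lead values.

    The stats TSV needs locus_id, variant_id, chrom, pos, ref, alt, is_lead
    and at least one of p / z; the LD TSV needs locus_id, variant_id,
    r2_to_lead and optionally population. Returns a dict keyed by locus_id
    with one validated DataFrame per locus.
    """
    stats = pd.read_csv(stats_path, sep="\t")
    ld = pd.read_csv(ld_path, sep="\t")
    required = {"locus_id", "variant_id", "chrom", "pos", "ref", "alt", "is_lead"}
    missing = required - set(stats.columns)
    if missing:
        raise FormatError(f"{stats_path}: missing column(s) {sorted(missing)}")
    if "p" not in stats.columns and "z" not in stats.columns:
        raise FormatError(f"{stats_path}: needs a 'p' or 'z' column")
    if "p" in stats.columns:
        pvals = stats["p"].dropna()
        if ((pvals <= 0) | (pvals > 1)).any():
            raise ValidationError(f"{stats_path}: p-values must be in (0, 1]")
    if {"locus_id", "variant_id", "r2_to_lead"} - set(ld.columns):
        raise FormatError(
            f"{ld_path}: needs locus_id, variant_id, r2_to_lead columns"
        )
    r2 = ld["r2_to_lead"].dropna()
    if ((r2 < 0) | (r2 > 1)).any():
        raise ValidationError(f"{ld_path}: r2_to_lead must be in [0, 1]")

    merged = stats.merge(
        ld, on=["locus_id", "variant_id"], how="left", validate="one_to_one"
    )
    out: dict[str, pd.DataFrame] = {}
    for locus_id, grp in merged.groupby("locus_id", sort=True):
        n_lead = int(grp["is_lead"].astype(bool).sum())
        if n_lead != 1:
            raise ValidationError(
                f"locus {locus_id}: expected exactly 1 lead variant, found {n_lead}"
            )
        out[str(locus_id)] = grp.reset_index(drop=True)
    return out


def write_gwas_bundle(
    stats: pd.DataFrame, ld: pd.DataFrame, stats_path: str | Path, ld_path: str | Path
) -> None:
    stats.to_csv(stats_path, sep="\t", index=False)
    ld.to_csv(ld_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# generic result tables


_SORT_KEYS = [
    "locus_id",
    "chrom",
    "pos",
    "peak_chrom",
    "peak_start",
    "start",
    "variant_id",
    "peak",
    "gene",
    "gene_id",
    "tf",
    "cell_type",
]


def records_to_frame(records: list) -> pd.DataFrame:
    """Flatten a homogeneous list of dataclass records into a DataFrame."""
    if not records:
        return pd.DataFrame()
    first = records[0]
    if is_dataclass(first):
        if len({type(r) for r in records}) != 1:
            raise ValidationError("records must be of one homogeneous type")
        rows = []
        for r in records:
            row = {}
            for f in dc_fields(r):
                v = getattr(r, f.name)
                row[f.name] = _scalarize(v)
            rows.append(row)
        return pd.DataFrame(rows)
    if isinstance(first, dict):
        return pd.DataFrame(records)
    raise ValidationError(f"cannot tabulate records of type {type(first)}")


def _scalarize(v):
    if isinstance(v, GenomicInterval):
        return str(v)
    if isinstance(v, Variant):
        return v.variant_id
    if isinstance(v, (list, tuple, set, frozenset)):
        return ";".join(sorted(str(_scalarize(x)) for x in v))
    if isinstance(v, float) and math.isnan(v):
        return v
    return v


def write_table(records: list | pd.DataFrame, out_path: str | Path) -> None:
    """Write records as a TSV with deterministic column and row order."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if len(df):
        keys = [k for k in _SORT_KEYS if k in df.columns]
        if keys:
            df = df.sort_values(keys, kind="mergesort").reset_index(drop=True)
    df.to_csv(out_path, sep="\t", index=False, float_format="%.8g")


# ---------------------------------------------------------------------------
# small helpers


def _read_lines(path: str | Path) -> list[str]:
    try:
        text = Path(path).read_text()
    except FileNotFoundError as exc:
        raise FormatError(f"missing required file {path}") from exc
    return [ln for ln in text.splitlines() if ln.strip()]
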