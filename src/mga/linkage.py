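"""Co-accessibility, cCRE modules, peak-gene links, and the six-level
cCRE->gene linkage hierarchy.

Sparse near-binary single-cell accessibility is densified by summing counts
over metacells (disjoint groups of k nearest neighbors in a TF-IDF +
truncated-SVD embedding, first component dropped as depth-correlated).
Co-accessibility between two peaks within 500 kb is the Pearson correlation
of their metacell counts; scores >= 0.32 define module edges (Louvain
communities of two or more peaks) and >= 0.5 "directly co-accessible" pairs.

A peak-gene link correlates peak accessibility with gene expression across
units and standardizes the correlation against n_background peaks matched
to the focal peak in (GC fraction, mean accessibility, width) z-space; the
background pool is genome-wide, so links retained at a small window are a
subset of those at a larger one. Retained links satisfy p < 0.05 and
|r| > 0.05.

Linkage levels, strongest last:
  1 module mate is a promoter cCRE          4 module mate has a gene link
  2 directly co-accessible with a promoter  5 directly co-accessible with a
  3 is itself a promoter cCRE                 gene-linked cCRE
                                            6 is itself gene-linked
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sps
from sklearn.decomposition import TruncatedSVD
from sklearn.neighbors import NearestNeighbors

from .types import GeneModel, GenomicInterval, MultiomeBundle

logger = logging.getLogger(__name__)

DEFAULT_METACELL_K = 50
DEFAULT_MAX_DIST = 500_000
MODULE_CUTOFF = 0.32
DIRECT_CUTOFF = 0.5
DEFAULT_WINDOW = 1_000_000
DEFAULT_MIN_CELLS = 10
DEFAULT_N_BACKGROUND = 200
DEFAULT_P_CUTOFF = 0.05
DEFAULT_R_CUTOFF = 0.05
SVD_COMPONENTS = 30


@dataclass
class Metacell:
    members: list[int]
    atac: np.ndarray
    rna: np.ndarray
    dominant_cell_type: str


@dataclass
class CoaccessPair:
    peak_i: int
    peak_j: int
    score: float
    distance: float


@dataclass
class CcreModule:
    module_id: int
    members: tuple[int, ...]


@dataclass
class PeakGeneLink:
    peak: int
    gene: str
    r: float
    z: float
    p: float
    tss_distance: float


@dataclass
class LinkageRecord:
    peak: int
    gene: str
    level: int
    evidence: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# embedding + metacells


def tfidf_svd_embedding(
    atac: sp.spmatrix,
    n_components: int = SVD_COMPONENTS,
    drop_first: bool = True,
    random_state: int = 0,
) -> np.ndarray:
    """TF-IDF normalize a cells x peaks matrix and embed with truncated SVD.

    The first component, which tracks per-cell depth, is dropped by default.
    """
    X = sp.csr_matrix(atac, dtype=float)
    n_cells, n_peaks = X.shape
    row = np.asarray(X.sum(axis=1)).ravel()
    row[row == 0] = 1.0
    tf = sp.diags(1.0 / row) @ X
    df = np.asarray((X > 0).sum(axis=0)).ravel().astype(float)
    idf = np.log(1 + n_cells / np.maximum(df, 1.0))
    mat = tf @ sp.diags(idf)
    k = min(n_components, min(mat.shape) - 1)
    svd = TruncatedSVD(n_components=k, random_state=random_state)
    emb = svd.fit_transform(mat)
    return emb[:, 1:] if drop_first else emb


def make_metacells(
    bundle: MultiomeBundle,
    k: int = DEFAULT_METACELL_K,
    random_state: int = 0,
) -> list[Metacell]:
    """Greedy disjoint grouping of k nearest neighbors into metacells.

    Produces floor(n_cells / k) metacells; leftover cells are not assigned.
    Seeds are taken in cell order, so the grouping is deterministic.
    """
    n = bundle.n_cells
    if n < k:
        raise ValueError(f"need at least k={k} cells, have {n}")
    if n < 2 * k:
        logger.warning("fewer than 2k cells; producing a single metacell split")
    emb = tfidf_svd_embedding(bundle.atac, random_state=random_state)
    nn = NearestNeighbors(n_neighbors=min(n, 4 * k)).fit(emb)
    _, nbrs = nn.kneighbors(emb)
    assigned = np.zeros(n, dtype=bool)
    A = bundle.atac.tocsr()
    R = bundle.rna.tocsr()
    types = bundle.cell_meta["cell_type"].to_numpy()
    out: list[Metacell] = []
    n_meta = n // k
    for seed in range(n):
        if len(out) >= n_meta:
            break
        if assigned[seed]:
            continue
        cand = [j for j in nbrs[seed] if not assigned[j]]
        if len(cand) < k:
            extra = np.flatnonzero(~assigned)
            d = np.linalg.norm(emb[extra] - emb[seed], axis=1)
            cand = list(extra[np.argsort(d, kind="stable")])
        members = sorted(int(j) for j in cand[:k])
        assigned[members] = True
        vals, counts = np.unique(types[members], return_counts=True)
        dominant = str(vals[np.argmax(counts)])
        out.append(
            Metacell(
                members=members,
                atac=np.asarray(A[members].sum(axis=0)).ravel(),
                rna=np.asarray(R[members].sum(axis=0)).ravel(),
                dominant_cell_type=dominant,
            )
        )
    return out


def metacell_matrices(metacells: list[Metacell]) -> tuple[np.ndarray, np.ndarray]:
    atac = np.vstack([m.atac for m in metacells])
    rna = np.vstack([m.rna for m in metacells])
    return atac, rna


# ---------------------------------------------------------------------------
# co-accessibility + modules


def coaccessibility(
    metacell_atac: np.ndarray,
    peaks: list[GenomicInterval],
    max_dist: int = DEFAULT_MAX_DIST,
) -> list[CoaccessPair]:
    """Pearson co-accessibility for peak pairs within max_dist of each other.

    Pairs where either peak has zero variance across metacells are omitted.
    """
    M = np.asarray(metacell_atac, dtype=float)
    if M.shape[0] < 10:
        raise ValueError("co-accessibility needs >= 10 metacells")
    mids = np.array([p.midpoint for p in peaks])
    chroms = np.array([p.chrom for p in peaks])
    sd = M.std(axis=0)
    Z = np.zeros_like(M)
    ok = sd > 0
    Z[:, ok] = (M[:, ok] - M[:, ok].mean(axis=0)) / sd[ok]
    out: list[CoaccessPair] = []
    for chrom in sorted(set(chroms)):
        idx = np.flatnonzero(chroms == chrom)
        order = idx[np.argsort(mids[idx], kind="stable")]
        m = mids[order]
        for a_pos, i in enumerate(order):
            if not ok[i]:
                continue
            hi = np.searchsorted(m, m[a_pos] + max_dist, side="right")
            js = order[a_pos + 1 : hi]
            js = js[ok[js]]
            if js.size == 0:
                continue
            r = Z[:, js].T @ Z[:, i] / M.shape[0]
            for j, rv in zip(js, r):
                if np.isfinite(rv):
                    lo_, hi_ = (int(i), int(j)) if mids[i] <= mids[j] else (int(j), int(i))
                    out.append(
                        CoaccessPair(
                            peak_i=lo_,
                            peak_j=hi_,
                            score=float(np.clip(rv, -1.0, 1.0)),
                            distance=float(abs(mids[j] - mids[i])),
                        )
                    )
    return out


def detect_modules(
    pairs: list[CoaccessPair],
    module_cutoff: float = MODULE_CUTOFF,
    seed: int = 0,
) -> list[CcreModule]:
    """Louvain communities (size >= 2) of the thresholded co-accessibility graph."""
    G = nx.Graph()
    for p in sorted(pairs, key=lambda q: (q.peak_i, q.peak_j)):
        if p.score >= module_cutoff:
            G.add_edge(p.peak_i, p.peak_j, weight=p.score)
    if G.number_of_edges() == 0:
        return []
    comms = nx.community.louvain_communities(G, weight="weight", seed=seed)
    comms = [tuple(sorted(c)) for c in comms if len(c) >= 2]
    comms.sort(key=lambda c: c[0])
    return [CcreModule(module_id=i, members=c) for i, c in enumerate(comms)]


def direct_pairs(
    pairs: list[CoaccessPair], direct_cutoff: float = DIRECT_CUTOFF
) -> dict[int, set[int]]:
    """Adjacency of "directly co-accessible" peaks (score >= 0.5)."""
    adj: dict[int, set[int]] = {}
    for p in pairs:
        if p.score >= direct_cutoff:
            adj.setdefault(p.peak_i, set()).add(p.peak_j)
            adj.setdefault(p.peak_j, set()).add(p.peak_i)
    return adj


# ---------------------------------------------------------------------------
# peak-gene links


def link_peaks_to_genes(
    unit_atac: np.ndarray,
    unit_rna: np.ndarray,
    peaks: list[GenomicInterval],
    genes: list[GeneModel],
    cell_atac: sp.spmatrix | None = None,
    cell_rna: sp.spmatrix | None = None,
    peak_gc: np.ndarray | None = None,
    window: int = DEFAULT_WINDOW,
    min_cells: int = DEFAULT_MIN_CELLS,
    n_background: int = DEFAULT_N_BACKGROUND,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    r_cutoff: float = DEFAULT_R_CUTOFF,
    two_sided: bool = False,
) -> list[PeakGeneLink]:
    """Background-corrected peak-gene expression links within a cis window.

    ``unit_atac``/``unit_rna`` are the correlation units (cells or
    metacells); ``cell_atac``/``cell_rna``, when given, provide the
    cell-level min_cells eligibility filter. The null for each (peak, gene)
    pair is the correlation of the ``n_background`` peaks nearest to the
    focal peak in standardized (GC, mean accessibility, width) space with
    the same gene.
    """
    A = np.asarray(unit_atac, dtype=float)
    R = np.asarray(unit_rna, dtype=float)
    m = A.shape[0]
    n_peaks, n_genes = A.shape[1], R.shape[1]

    ca = cell_atac if cell_atac is not None else sp.csr_matrix(A)
    cr = cell_rna if cell_rna is not None else sp.csr_matrix(R)
    peak_cells = np.asarray((ca > 0).sum(axis=0)).ravel()
    gene_cells = np.asarray((cr > 0).sum(axis=0)).ravel()
    peak_ok = peak_cells >= min_cells
    gene_ok = gene_cells >= min_cells

    sd_a = A.std(axis=0)
    sd_r = R.std(axis=0)
    peak_ok &= sd_a > 0
    Za = np.zeros_like(A)
    Za[:, peak_ok] = (A[:, peak_ok] - A[:, peak_ok].mean(axis=0)) / sd_a[peak_ok]
    Zr = np.zeros((m, n_genes))
    gene_var_ok = gene_ok & (sd_r > 0)
    for g in np.flatnonzero(gene_ok & ~(sd_r > 0)):
        logger.warning("gene %s has zero-variance expression; skipped", genes[g].gene_id)
    Zr[:, gene_var_ok] = (
        R[:, gene_var_ok] - R[:, gene_var_ok].mean(axis=0)
    ) / sd_r[gene_var_ok]

    # genome-wide background matching in (GC, mean accessibility, width) z-space
    eligible = np.flatnonzero(peak_ok)
    if eligible.size == 0:
        return []
    feats = [
        np.asarray((ca > 0).mean(axis=0)).ravel(),
        np.array([p.width for p in peaks], dtype=float),
    ]
    if peak_gc is not None:
        feats.insert(0, np.asarray(peak_gc, dtype=float))
    F = np.column_stack(feats)[eligible]
    F = (F - F.mean(axis=0)) / np.where(F.std(axis=0) > 0, F.std(axis=0), 1.0)
    nb = min(n_background, eligible.size - 1)
    if nb < n_background:
        logger.warning(
            "only %d candidate background peaks available (requested %d)",
            nb,
            n_background,
        )
    if nb < 2:
        raise ValueError("background matching needs at least 2 candidate peaks")
    nn = NearestNeighbors(n_neighbors=nb + 1).fit(F)
    _, nbr_local = nn.kneighbors(F)
    bg_of: dict[int, np.ndarray] = {}
    for li, pi in enumerate(eligible):
        row = eligible[nbr_local[li]]
        bg_of[int(pi)] = row[row != pi][:nb]

    Rmat = Za.T @ Zr / m  # peaks x genes correlations

    mids = np.array([p.midpoint for p in peaks])
    chroms = np.array([p.chrom for p in peaks])
    out: list[PeakGeneLink] = []
    for g in np.flatnonzero(gene_var_ok):
        gene = genes[g]
        cand = np.flatnonzero(
            peak_ok & (chroms == gene.chrom) & (np.abs(mids - gene.tss) <= window)
        )
        if cand.size == 0:
            continue
        bg_idx = np.vstack([bg_of[int(j)] for j in cand])
        null = Rmat[bg_idx, g]
        mu = null.mean(axis=1)
        sdv = null.std(axis=1, ddof=1)
        for ci, j in enumerate(cand):
            r = float(Rmat[j, g])
            if sdv[ci] <= 0:
                continue
            z = (r - mu[ci]) / sdv[ci]
            p = 2 * sps.norm.sf(abs(z)) if two_sided else float(sps.norm.sf(z))
            # rank-based companion condition: r must also clear the same
            # quantile of the matched-background correlations, which keeps
            # the retention rule calibrated without distributional assumptions
            p_emp = (1 + int((null[ci] >= r).sum())) / (null.shape[1] + 1)
            if p < p_cutoff and p_emp < p_cutoff and abs(r) > r_cutoff:
                out.append(
                    PeakGeneLink(
                        peak=int(j),
                        gene=gene.gene_id,
                        r=r,
                        z=float(z),
                        p=float(p),
                        tss_distance=float(mids[j] - gene.tss),
                    )
                )
    out.sort(key=lambda l: (l.gene, l.peak))
    return out


def wide_window_links(*args, window: int = 2_000_000, **kwargs) -> list[PeakGeneLink]:
    """link_peaks_to_genes at the wider +/-2 or +/-5 Mb cis windows."""
    return link_peaks_to_genes(*args, window=window, **kwargs)


# ---------------------------------------------------------------------------
# level assignment


def assign_linkage_level(
    ccres: list[int],
    modules: list[CcreModule],
    direct: dict[int, set[int]],
    promoter_genes: dict[int, tuple[str, ...]],
    links: list[PeakGeneLink],
) -> list[LinkageRecord]:
    """Evaluate all six level predicates for each CCV-colocalizing cCRE.

    Returns one record per (cCRE, gene) carrying the maximum attained level
    and the full evidence chain of every satisfied predicate.
    """
    module_of: dict[int, CcreModule] = {}
    for mod in modules:
        for pk in mod.members:
            module_of[pk] = mod
    links_of: dict[int, list[PeakGeneLink]] = {}
    for ln in links:
        links_of.setdefault(ln.peak, []).append(ln)

    out: list[LinkageRecord] = []
    for ccre in ccres:
        evidence: dict[str, list[tuple[int, str]]] = {}

        def add(gene: str, level: int, note: str) -> None:
            evidence.setdefault(gene, []).append((level, note))

        mod = module_of.get(ccre)
        if mod is not None:
            for mate in mod.members:
                if mate == ccre:
                    continue
                for gene in promoter_genes.get(mate, ()):  # L1
                    add(gene, 1, f"L1:module{mod.module_id}:promoter_peak{mate}")
                for ln in links_of.get(mate, []):  # L4
                    add(ln.gene, 4, f"L4:module{mod.module_id}:linked_peak{mate}")
        for partner in sorted(direct.get(ccre, ())):
            for gene in promoter_genes.get(partner, ()):  # L2
                add(gene, 2, f"L2:direct:promoter_peak{partner}")
            for ln in links_of.get(partner, []):  # L5
                add(ln.gene, 5, f"L5:direct:linked_peak{partner}")
        for gene in promoter_genes.get(ccre, ()):  # L3
            add(gene, 3, "L3:is_promoter")
        for ln in links_of.get(ccre, []):  # L6
            add(ln.gene, 6, "L6:gene_linked")

        for gene in sorted(evidence):
            evs = sorted(evidence[gene])
            out.append(
                LinkageRecord(
                    peak=ccre,
                    gene=gene,
                    level=max(l for l, _ in evs),
                    evidence=[note for _, note in evs],
                )
            )
    out.sort(key=lambda r: (r.peak, r.gene))
    return out


def gc_fraction(genome, peaks: list[GenomicInterval]) -> np.ndarray:
    """Per-peak GC fraction from a dict-of-strings or pyfaidx genome."""
    from .tf_allelics import _fetch

    out = np.zeros(len(peaks))
    for i, p in enumerate(peaks):
        seq = _fetch(genome, p.chrom, p.start, p.end)
        if seq:
            out[i] = (seq.count("G") + seq.count("C")) / len(seq)
    return out
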