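"""Synthetic multiome generator with planted, recorded ground truth.

Emulates — at desk scale — the structure of a lung single-cell multiome
study: 23 cell types in four unbalanced categories, near-binary cell-type-
patterned peak accessibility, negative-binomial expression with planted
peak->gene effects, AR(1)-LD GWAS loci with one planted causal variant each,
motif-planted sequences carrying allelic variants, and fragment-level Tn5
insertions with planted footprint protection over a smooth positional bias
field. Everything planted is recorded in a :class:`SyntheticTruth` so every
downstream stage can be scored against ground truth without external data.

Two genome layouts are provided. ``dense`` packs peaks every ~2 kb on a few
compact chromosomes and is the default pipeline condition. ``islands``
places one gene, one distal enhancer peak, and a few unlinked peaks per
widely separated island; it is the geometry used for peak-gene linkage
calibration experiments, where window-level sparsity makes planted-link
recovery a well-posed question at desk scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sps

from .types import (
    CATEGORIES,
    GeneModel,
    GenomicInterval,
    MultiomeBundle,
    PWM,
    ValidationError,
)

_TYPE_PREFIX = {
    "epithelial": "epi",
    "immune": "imm",
    "endothelial": "endo",
    "stromal": "stro",
}


class ConfigError(ValueError):
    """Raised when a SimConfig is internally inconsistent."""


@dataclass
class SimConfig:
    """Generator parameters. Defaults are the study conditions."""

    # cell population: 8 epithelial, 7 immune, 4 endothelial, 4 stromal types
    cell_types_per_category: dict = field(
        default_factory=lambda: {
            "epithelial": 8,
            "immune": 7,
            "endothelial": 4,
            "stromal": 4,
        }
    )
    cells_per_type: int = 180
    n_samples: int = 4

    # genome layout
    layout: str = "dense"  # "dense" | "islands"
    n_chroms: int = 2
    n_peaks: int = 5000
    peak_width_mean: float = 600.0
    peak_width_sd: float = 40.0
    peak_width_min: int = 560
    peak_spacing: float = 2000.0  # mean gap between peaks (dense layout)
    island_null_peaks: int = 1
    island_enhancers_per_gene: int = 2
    island_enhancer_dist: tuple = (10_000, 300_000)
    island_separation: int = 11_000_000

    # accessibility
    p_open_high: float = 0.8
    p_open_low: float = 0.02
    depth_sigma: float = 0.25
    frac_single_type: float = 0.35
    frac_single_category: float = 0.40

    # expression
    n_genes: int = 1000
    nb_mean: float = 2.0
    nb_dispersion: float = 2.0  # NB size parameter
    marker_genes_per_type: int = 1
    marker_high: float = 6.0
    marker_low: float = 0.1
    n_links: int = 60
    link_effect: float = 3.0
    link_max_dist: int = 500_000

    # GWAS
    n_loci: int = 10
    variants_per_locus: int = 50
    ld_rho: float = 0.95
    causal_z: float = 7.0
    variant_spacing: int = 700
    trait_category: str = "epithelial"

    # sequences and motifs
    n_tfs: int = 2
    motif_width: int = 8
    footprint_sites_per_tf: int = 30
    gc_content: float = 0.41

    # fragments
    mean_fragments_per_open: float = 3.0
    protection_factor: float = 0.2
    flank_boost: float = 1.0
    flank_sigma: float = 100.0
    bias_amplitude: float = 0.15
    bias_period: float = 190.0
    fragment_peaks: str = "motif"  # "motif" | "all"

    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_open_high, self.p_open_low):
            if not 0 <= p <= 1:
                raise ConfigError(f"open probability {p} outside [0, 1]")
        if not 0 <= self.ld_rho < 1:
            raise ConfigError(f"ld_rho must be in [0, 1), got {self.ld_rho}")
        if self.causal_z < 0:
            raise ConfigError("causal_z must be >= 0")
        if not 0 <= self.protection_factor <= 1:
            raise ConfigError("protection_factor must be in [0, 1]")
        if self.frac_single_type + self.frac_single_category > 1:
            raise ConfigError("pattern fractions sum above 1")
        if self.trait_category not in CATEGORIES:
            raise ConfigError(f"unknown trait_category {self.trait_category}")
        if self.layout not in ("dense", "islands"):
            raise ConfigError(f"unknown layout {self.layout}")
        n_types = sum(self.cell_types_per_category.values())
        if self.n_genes < self.marker_genes_per_type * n_types + self.n_tfs:
            raise ConfigError("n_genes too small for marker + TF genes")


@dataclass
class TruthLocus:
    locus_id: str
    chrom: str
    causal_index: int
    causal_variant_id: str
    variant_ids: list
    positions: list
    in_peak: dict  # variant_id -> peak index (only variants inside peaks)


@dataclass
class SyntheticTruth:
    """Planted ground truth, reproducible from (SimConfig, seed)."""

    seed: int
    cell_types: list = field(default_factory=list)
    type_category: dict = field(default_factory=dict)
    cells_per_category: dict = field(default_factory=dict)
    peak_patterns: list = field(default_factory=list)  # per peak: set of types
    peak_categories: list = field(default_factory=list)  # planted category set
    promoter_peak_of_gene: dict = field(default_factory=dict)  # gene_id -> peak idx
    marker_genes: dict = field(default_factory=dict)  # gene_id -> cell types
    links: list = field(default_factory=list)  # (peak_idx, gene_id, effect)
    loci: list = field(default_factory=list)  # TruthLocus
    allelic_variants: list = field(default_factory=list)  # (variant_id, tf, direction)
    footprint_sites: dict = field(default_factory=dict)
    # tf -> {"cell_types": [...], "peaks": [...], "occurrences": [(chrom,s,e)]}
    trait_category: str = ""
    bias_params: dict = field(default_factory=dict)
    emitted_fragments: int = 0
    open_entries: int = 0

    def bias_model(self):
        amp = self.bias_params.get("amplitude", 0.0)
        period = self.bias_params.get("period", 1.0)
        phases = self.bias_params.get("phase", {})

        def model(chrom, positions):
            pos = np.asarray(positions, dtype=float)
            return 1.0 + amp * np.sin(
                2 * np.pi * (pos + phases.get(chrom, 0.0)) / period
            )

        return model


def default_motifs(config: SimConfig) -> list[PWM]:
    """The generator's built-in motif set, derived deterministically from the seed.

    Each motif has one high-information anchor position (consensus A at
    probability 0.97) carrying most of the scoring weight, so substituting
    the anchor base moves the relative binding score by more than the 0.7
    allelic threshold, and moderately informative C/G positions elsewhere.
    Keeping non-anchor consensus bases (and planted flanks) off A/T ensures
    no spurious anchor alignment exists near a planted site on either strand.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    pwms = []
    for i in range(config.n_tfs):
        w = config.motif_width
        base_choices = np.array([1, 2])  # C, G
        consensus = rng.choice(base_choices, size=w)
        probs = np.full((4, w), (1 - 0.45) / 3)
        probs[consensus, np.arange(w)] = 0.45
        anchor = int(rng.integers(0, w))
        probs[:, anchor] = 0.01
        probs[0, anchor] = 0.97  # anchor consensus A
        pwms.append(PWM(name=f"simTF{i + 1}", probs=probs / probs.sum(axis=0)))
    return pwms


class Simulator:
    """Stage-wise synthetic data generator sharing one truth record.

    Stage randomness is drawn from per-stage child generators spawned from
    the config seed, so each stage is deterministic regardless of which
    other stages run.
    """

    def __init__(self, config: SimConfig | None = None):
        self.config = config or SimConfig()
        cfg = self.config
        self._rngs = {
            name: np.random.default_rng(np.random.SeedSequence([cfg.seed, salt]))
            for name, salt in [
                ("layout", 1),
                ("atac", 2),
                ("rna", 3),
                ("gwas", 4),
                ("seq", 5),
                ("frag", 6),
            ]
        }
        self.truth = SyntheticTruth(seed=cfg.seed, trait_category=cfg.trait_category)
        self._build_population()
        self._build_layout()
        self._bundle: MultiomeBundle | None = None
        self._gwas: tuple[pd.DataFrame, pd.DataFrame] | None = None
        self._genome: dict[str, str] | None = None

    # ------------------------------------------------------------------ layout

    def _build_population(self) -> None:
        cfg = self.config
        types, type_cat = [], {}
        for cat in CATEGORIES:
            n = cfg.cell_types_per_category.get(cat, 0)
            for i in range(n):
                t = f"{_TYPE_PREFIX[cat]}{i + 1}"
                types.append(t)
                type_cat[t] = cat
        self.cell_types = types
        self.type_category = type_cat
        self.cells = []
        self.cell_type_of = []
        for t in types:
            for j in range(cfg.cells_per_type):
                self.cells.append(f"{t}_c{j:04d}")
                self.cell_type_of.append(t)
        self.cell_type_of = np.array(self.cell_type_of)
        self.truth.cell_types = list(types)
        self.truth.type_category = dict(type_cat)
        counts = {c: 0 for c in CATEGORIES}
        for t in types:
            counts[type_cat[t]] += cfg.cells_per_type
        self.truth.cells_per_category = counts

    def _draw_pattern(self, rng) -> frozenset:
        cfg = self.config
        u = rng.random()
        cats = list(cfg.cell_types_per_category)
        sizes = np.array([cfg.cell_types_per_category[c] for c in cats], dtype=float)
        by_cat = {
            c: [t for t in self.cell_types if self.type_category[t] == c]
            for c in cats
        }
        if u < cfg.frac_single_type:
            return frozenset([self.cell_types[rng.integers(len(self.cell_types))]])
        if u < cfg.frac_single_type + cfg.frac_single_category:
            cat = cats[rng.choice(len(cats), p=sizes / sizes.sum())]
            pool = by_cat[cat]
            k = int(rng.integers(2, len(pool) + 1))
            return frozenset(rng.choice(pool, size=k, replace=False).tolist())
        while True:
            k = int(rng.integers(2, len(self.cell_types) + 1))
            picked = frozenset(
                rng.choice(self.cell_types, size=k, replace=False).tolist()
            )
            if len({self.type_category[t] for t in picked}) >= 2:
                return picked

    def _planted_categories(self, pattern: frozenset) -> frozenset:
        cats = {self.type_category[t] for t in pattern}
        return frozenset(cats) if len(cats) == 1 else frozenset()

    def _build_layout(self) -> None:
        cfg = self.config
        rng = self._rngs["layout"]
        if cfg.layout == "dense":
            self._build_dense_layout(rng)
        else:
            self._build_island_layout(rng)
        self.truth.peak_patterns = [set(p) for p in self.patterns]
        self.truth.peak_categories = [
            set(self._planted_categories(p)) for p in self.patterns
        ]
        self.truth.promoter_peak_of_gene = dict(self.promoter_peak_of_gene)
        self.truth.marker_genes = {
            g: sorted(ts) for g, ts in self.marker_genes.items()
        }
        self.truth.links = [
            (int(pi), gid, float(eff)) for pi, gid, eff in self.links
        ]

    def _peak_width(self, rng) -> int:
        cfg = self.config
        w = int(round(rng.normal(cfg.peak_width_mean, cfg.peak_width_sd)))
        return max(cfg.peak_width_min, w)

    def _build_dense_layout(self, rng) -> None:
        cfg = self.config
        peaks: list[GenomicInterval] = []
        per_chrom = int(math.ceil(cfg.n_peaks / cfg.n_chroms))
        for ci in range(cfg.n_chroms):
            chrom = f"chr{ci + 1}"
            pos = 1000
            n_here = min(per_chrom, cfg.n_peaks - len(peaks))
            for _ in range(n_here):
                gap = int(rng.exponential(cfg.peak_spacing)) + 200
                w = self._peak_width(rng)
                peaks.append(GenomicInterval(chrom, pos + gap, pos + gap + w))
                pos = pos + gap + w
        self.peaks = peaks
        self.patterns = [self._draw_pattern(rng) for _ in peaks]

        # genes: promoter peak chosen among peaks, TSS at the peak center
        n_types = len(self.cell_types)
        n_markers = cfg.marker_genes_per_type * n_types
        gene_peaks = rng.choice(len(peaks), size=cfg.n_genes, replace=False)
        gene_peaks = np.sort(gene_peaks)
        genes: list[GeneModel] = []
        marker_genes: dict[str, frozenset] = {}
        promoter_peak_of_gene: dict[str, int] = {}
        marker_iter = [
            t for t in self.cell_types for _ in range(cfg.marker_genes_per_type)
        ]
        tf_names = [f"simTF{i + 1}" for i in range(cfg.n_tfs)]
        self.tf_bound_types: dict[str, frozenset] = {}
        cats_cycle = list(CATEGORIES)
        for i, tf in enumerate(tf_names):
            cat = cats_cycle[i % len(cats_cycle)]
            pool = [t for t in self.cell_types if self.type_category[t] == cat]
            k = min(2, len(pool))
            self.tf_bound_types[tf] = frozenset(
                rng.choice(pool, size=k, replace=False).tolist()
            )
        for gi, pj in enumerate(gene_peaks):
            peak = peaks[pj]
            strand = "+" if rng.random() < 0.5 else "-"
            tss = int(peak.midpoint)
            is_marker = gi < n_markers
            # markers get compact bodies so their local chromatin domain
            # (promoter + body peaks, patterned below) stays cell-type specific
            length = int(rng.integers(5_000, 10_000 if is_marker else 50_000))
            gene_id = f"G{gi:05d}"
            if is_marker:
                t = marker_iter[gi]
                name = f"MARKER_{t}"
                marker_genes[gene_id] = frozenset([t])
                self.patterns[pj] = frozenset([t])
            elif gi < n_markers + cfg.n_tfs:
                tf = tf_names[gi - n_markers]
                name = tf
                marker_genes[gene_id] = self.tf_bound_types[tf]
            else:
                name = f"gene{gi}"
            if strand == "+":
                tss_, tes_ = tss, tss + length
            else:
                tss_, tes_ = tss + length, tss
            genes.append(
                GeneModel(gene_id, name, peak.chrom, strand, tss_, tes_)
            )
            promoter_peak_of_gene[gene_id] = int(pj)
        self.genes = genes
        self.marker_genes = marker_genes
        self.promoter_peak_of_gene = promoter_peak_of_gene

        # marker genes sit in cell-type-specific chromatin domains: peaks in
        # their promoter/gene-body window share the marker's pattern
        for gene in genes:
            tset = marker_genes.get(gene.gene_id)
            if not tset or len(tset) != 1:
                continue
            lo = min(gene.tss, gene.tes) - 2000
            hi = max(gene.tss, gene.tes)
            for j, p in enumerate(peaks):
                if p.chrom == gene.chrom and lo <= p.midpoint <= hi:
                    self.patterns[j] = tset

        # planted distal peak -> gene links on non-marker genes
        links = []
        candidates = [
            g for g in genes if g.gene_id not in marker_genes
        ]
        rng.shuffle(candidates)
        peak_starts = np.array([p.start for p in peaks])
        peak_chroms = np.array([p.chrom for p in peaks])
        used_peaks: set[int] = set(promoter_peak_of_gene.values())
        for g in candidates:
            if len(links) >= cfg.n_links:
                break
            near = np.flatnonzero(
                (peak_chroms == g.chrom)
                & (np.abs(peak_starts - g.tss) <= cfg.link_max_dist)
            )
            near = [int(j) for j in near if int(j) not in used_peaks]
            if not near:
                continue
            pj = int(near[int(rng.integers(len(near)))])
            used_peaks.add(pj)
            links.append((pj, g.gene_id, cfg.link_effect))
        self.links = links

    def _build_island_layout(self, rng) -> None:
        """One gene + one planted enhancer + null peaks per isolated island."""
        cfg = self.config
        peaks: list[GenomicInterval] = []
        genes: list[GeneModel] = []
        patterns: list[frozenset] = []
        links: list[tuple] = []
        marker_genes: dict[str, frozenset] = {}
        promoter_peak_of_gene: dict[str, int] = {}
        chrom = "chr1"
        base = 100_000
        lo_d, hi_d = cfg.island_enhancer_dist
        self.tf_bound_types = {}
        for gi in range(cfg.n_genes):
            gene_id = f"G{gi:05d}"
            w = self._peak_width(rng)
            prom = GenomicInterval(chrom, base, base + w)
            peaks.append(prom)
            patterns.append(self._draw_pattern(rng))
            promoter_peak_of_gene[gene_id] = len(peaks) - 1
            tss = int(prom.midpoint)
            genes.append(
                GeneModel(gene_id, f"gene{gi}", chrom, "+", tss, tss + 20_000)
            )
            # a gene's enhancers share one planted pattern, so coinherited
            # regulatory peaks are mutually co-accessible (module structure)
            island_pattern = self._draw_pattern(rng)
            for _ in range(cfg.island_enhancers_per_gene):
                if len(links) >= cfg.n_links:
                    break
                d = int(rng.integers(lo_d, hi_d))
                w2 = self._peak_width(rng)
                enh = GenomicInterval(chrom, base + d, base + d + w2)
                peaks.append(enh)
                patterns.append(island_pattern)
                links.append((len(peaks) - 1, gene_id, cfg.link_effect))
            for k in range(cfg.island_null_peaks):
                d = int(rng.integers(lo_d, hi_d))
                w3 = self._peak_width(rng)
                null = GenomicInterval(chrom, base + d + 5_000 * (k + 1),
                                       base + d + 5_000 * (k + 1) + w3)
                peaks.append(null)
                patterns.append(self._draw_pattern(rng))
            base += cfg.island_separation
        self.peaks = peaks
        self.patterns = patterns
        self.genes = genes
        self.links = links
        self.marker_genes = marker_genes
        self.promoter_peak_of_gene = promoter_peak_of_gene

    # ------------------------------------------------------------------ multiome

    def multiome(self) -> MultiomeBundle:
        if self._bundle is not None:
            return self._bundle
        cfg = self.config
        rng = self._rngs["atac"]
        n_cells = len(self.cells)
        n_peaks = len(self.peaks)
        depth = np.exp(rng.normal(0.0, cfg.depth_sigma, size=n_cells))
        depth = np.clip(depth, 0.4, 1.0 / max(cfg.p_open_high, 1e-9))
        self.depth = depth

        # peak x type membership matrix
        type_index = {t: i for i, t in enumerate(self.cell_types)}
        member = np.zeros((n_peaks, len(self.cell_types)), dtype=bool)
        for j, pat in enumerate(self.patterns):
            for t in pat:
                member[j, type_index[t]] = True

        rows, cols = [], []
        cell_type_idx = np.array([type_index[t] for t in self.cell_type_of])
        for ti in range(len(self.cell_types)):
            cmask = np.flatnonzero(cell_type_idx == ti)
            if cmask.size == 0:
                continue
            p_vec = np.where(member[:, ti], cfg.p_open_high, cfg.p_open_low)
            probs = depth[cmask][:, None] * p_vec[None, :]
            draws = rng.random((cmask.size, n_peaks)) < probs
            r, c = np.nonzero(draws)
            rows.append(cmask[r])
            cols.append(c)
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        atac = sp.csr_matrix(
            (np.ones(len(rows), dtype=np.int64), (rows, cols)),
            shape=(n_cells, n_peaks),
        )
        self.truth.open_entries = int(atac.nnz)

        rna = self._expression(atac)
        meta = pd.DataFrame(
            {
                "cell_id": self.cells,
                "sample_id": [
                    f"s{(hash_i % cfg.n_samples) + 1}"
                    for hash_i in range(n_cells)
                ],
                "cell_type": self.cell_type_of,
                "category": [self.type_category[t] for t in self.cell_type_of],
                "smoking_status": [
                    "ever" if (i % cfg.n_samples) < cfg.n_samples / 2 else "never"
                    for i in range(n_cells)
                ],
            }
        ).set_index("cell_id")
        self._bundle = MultiomeBundle(
            cells=list(self.cells),
            peaks=list(self.peaks),
            genes=list(self.genes),
            atac=atac,
            rna=rna,
            cell_meta=meta,
        )
        return self._bundle

    def _expression(self, atac: sp.csr_matrix) -> sp.csr_matrix:
        cfg = self.config
        rng = self._rngs["rna"]
        n_cells = len(self.cells)
        genes = self.genes
        base = np.exp(rng.normal(math.log(cfg.nb_mean), 0.4, size=len(genes)))
        rna_depth = np.exp(rng.normal(0.0, cfg.depth_sigma, size=n_cells))
        mu = rna_depth[:, None] * base[None, :]

        type_of_cell = self.cell_type_of
        for gi, g in enumerate(genes):
            tset = self.marker_genes.get(g.gene_id)
            if tset:
                mult = np.where(
                    np.isin(type_of_cell, list(tset)), cfg.marker_high, cfg.marker_low
                )
                mu[:, gi] = mu[:, gi] * mult

        gene_index = {g.gene_id: i for i, g in enumerate(genes)}
        A = atac.tocsc()
        for pj, gene_id, eff in self.links:
            gi = gene_index[gene_id]
            open_cells = np.asarray(
                (A[:, pj] > 0).todense()
            ).ravel()
            mu[open_cells, gi] *= eff

        r = cfg.nb_dispersion
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)
        return sp.csr_matrix(counts)

    # ------------------------------------------------------------------ GWAS

    def gwas(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Per-locus association stats and LD-to-lead tables."""
        if self._gwas is not None:
            return self._gwas
        cfg = self.config
        rng = self._rngs["gwas"]
        m = cfg.variants_per_locus
        # candidate causal peaks: planted trait-category peaks
        trait_peaks = [
            j
            for j, cats in enumerate(self.truth.peak_categories)
            if cats == {cfg.trait_category}
        ]
        if len(trait_peaks) < cfg.n_loci:
            raise ConfigError(
                f"not enough {cfg.trait_category} peaks "
                f"({len(trait_peaks)}) for {cfg.n_loci} loci"
            )
        causal_peaks = rng.choice(trait_peaks, size=cfg.n_loci, replace=False)
        self.causal_peaks = [int(j) for j in causal_peaks]

        stats_rows, ld_rows = [], []
        idx = np.arange(m)
        R = cfg.ld_rho ** np.abs(idx[:, None] - idx[None, :])
        try:
            L = np.linalg.cholesky(R + 1e-12 * np.eye(m))
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise ConfigError("LD matrix not positive definite") from exc

        peak_arr_start = np.array([p.start for p in self.peaks])
        peak_arr_end = np.array([p.end for p in self.peaks])
        peak_chroms = np.array([p.chrom for p in self.peaks])
        for li, pj in enumerate(self.causal_peaks):
            locus_id = f"{li + 1}_L{li + 1}"
            peak = self.peaks[pj]
            causal_idx = int(rng.integers(m // 4, 3 * m // 4)) if m >= 4 else 0
            causal_pos = int(peak.midpoint)  # 1-based position inside the peak
            positions = (
                causal_pos
                + (idx - causal_idx) * cfg.variant_spacing
                + rng.integers(-cfg.variant_spacing // 4,
                               cfg.variant_spacing // 4 + 1, size=m)
            )
            positions[causal_idx] = causal_pos
            positions = np.maximum(positions, 1)
            z = cfg.causal_z * R[:, causal_idx] + L @ rng.standard_normal(m)
            lead_idx = int(np.argmax(np.abs(z)))
            r2_lead = R[:, lead_idx] ** 2
            pvals = 2 * sps.norm.sf(np.abs(z))
            pvals = np.clip(pvals, 1e-300, 1.0)

            variant_ids = [f"rs{li + 1:02d}{k:04d}" for k in range(m)]
            in_peak = {}
            for k in range(m):
                hits = np.flatnonzero(
                    (peak_chroms == peak.chrom)
                    & (peak_arr_start < positions[k])
                    & (positions[k] <= peak_arr_end)
                )
                if hits.size:
                    in_peak[variant_ids[k]] = int(hits[0])
                stats_rows.append(
                    {
                        "locus_id": locus_id,
                        "variant_id": variant_ids[k],
                        "chrom": peak.chrom,
                        "pos": int(positions[k]),
                        # provisional alleles; finalized by the sequence stage
                        "ref": "A",
                        "alt": "C",
                        "z": float(z[k]),
                        "p": float(pvals[k]),
                        "is_lead": k == lead_idx,
                        "is_conditional": False,
                    }
                )
                ld_rows.append(
                    {
                        "locus_id": locus_id,
                        "variant_id": variant_ids[k],
                        "r2_to_lead": float(r2_lead[k]),
                        "population": "ALL",
                    }
                )
            self.truth.loci.append(
                TruthLocus(
                    locus_id=locus_id,
                    chrom=peak.chrom,
                    causal_index=causal_idx,
                    causal_variant_id=variant_ids[causal_idx],
                    variant_ids=variant_ids,
                    positions=[int(x) for x in positions],
                    in_peak=in_peak,
                )
            )
        stats = pd.DataFrame(stats_rows)
        ld = pd.DataFrame(ld_rows)
        self._gwas = (stats, ld)
        return self._gwas

    # ------------------------------------------------------------------ sequences

    def sequences(self) -> tuple[dict[str, str], pd.DataFrame]:
        """Genome FASTA dict + finalized variant alleles; plants motifs.

        Must run after :meth:`gwas` (variant positions define allelic sites).
        """
        if self._genome is not None:
            return self._genome, self._gwas[0]
        cfg = self.config
        rng = self._rngs["seq"]
        if self._gwas is None:
            self.gwas()
        pwms = default_motifs(cfg)
        pwm_by_name = {p.name: p for p in pwms}

        chrom_len: dict[str, int] = {}
        for p in self.peaks:
            chrom_len[p.chrom] = max(chrom_len.get(p.chrom, 0), p.end + 1000)
        for locus in self.truth.loci:
            chrom_len[locus.chrom] = max(
                chrom_len.get(locus.chrom, 0), max(locus.positions) + 1000
            )
        total = sum(chrom_len.values())
        if total > 100_000_000:
            raise ConfigError(
                f"genome of {total} bp is too large to synthesize; "
                "use the dense layout or fewer/smaller chromosomes"
            )
        gc = cfg.gc_content
        base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        genome_arr: dict[str, np.ndarray] = {}
        for chrom, ln in sorted(chrom_len.items()):
            genome_arr[chrom] = rng.choice(
                np.frombuffer(b"ACGT", dtype="S1"), size=ln, p=base_p
            )

        # plant footprint motif sites in peaks detected in the TF's bound types
        self.motif_occurrences: dict[str, list[GenomicInterval]] = {}
        causal_set = set(getattr(self, "causal_peaks", []))
        used_sites: set[int] = set()
        for tf, bound in getattr(self, "tf_bound_types", {}).items():
            pwm = pwm_by_name[tf]
            cons = pwm.consensus
            eligible = [
                j
                for j, pat in enumerate(self.patterns)
                if bound <= pat and j not in causal_set and j not in used_sites
            ]
            rng.shuffle(eligible)
            chosen = eligible[: cfg.footprint_sites_per_tf]
            used_sites.update(chosen)
            occs = []
            for j in chosen:
                peak = self.peaks[j]
                start = int(peak.midpoint) - pwm.width // 2
                self._write_seq(genome_arr, peak.chrom, start, cons)
                occs.append(GenomicInterval(peak.chrom, start, start + pwm.width))
            self.motif_occurrences[tf] = occs
            self.truth.footprint_sites[tf] = {
                "cell_types": sorted(bound),
                "peaks": [int(j) for j in chosen],
                "occurrences": [(o.chrom, o.start, o.end) for o in occs],
            }

        # plant one allelic (disrupting) variant per locus: the causal variant
        # sits at the max-IC position of a motif planted in its causal peak
        stats = self._gwas[0].copy()
        tf_names = sorted(pwm_by_name)
        for li, locus in enumerate(self.truth.loci):
            tf = tf_names[li % len(tf_names)]
            pwm = pwm_by_name[tf]
            max_ic = int(np.argmax(pwm.ic))
            causal_pos = locus.positions[locus.causal_index]  # 1-based
            motif_start0 = causal_pos - 1 - max_ic
            # flanks from C/G so no shifted window re-creates the A anchor
            flank_n = pwm.width - 1
            flanks = rng.choice(np.frombuffer(b"CG", dtype="S1"), size=2 * flank_n)
            planted = (
                flanks[:flank_n].tobytes().decode()
                + pwm.consensus
                + flanks[flank_n:].tobytes().decode()
            )
            self._write_seq(genome_arr, locus.chrom, motif_start0 - flank_n, planted)
            ref_base = pwm.consensus[max_ic]
            alt_base = "ACGT"[int(np.argmin(pwm.probs[:, max_ic]))]
            sel = (stats["locus_id"] == locus.locus_id) & (
                stats["variant_id"] == locus.causal_variant_id
            )
            stats.loc[sel, ["ref", "alt"]] = [ref_base, alt_base]
            self.truth.allelic_variants.append(
                (locus.causal_variant_id, tf, "disrupt")
            )
            self.truth.footprint_sites.setdefault(tf, {}).setdefault(
                "occurrences", []
            )

        # remaining variants: ref from the genome, alt a random other base
        causal_ids = {l.causal_variant_id for l in self.truth.loci}
        for locus in self.truth.loci:
            arr = genome_arr[locus.chrom]
            for vid, pos in zip(locus.variant_ids, locus.positions):
                if vid in causal_ids:
                    continue
                sel = (stats["locus_id"] == locus.locus_id) & (
                    stats["variant_id"] == vid
                )
                ref = arr[pos - 1].decode()
                others = [b for b in "ACGT" if b != ref]
                alt = others[int(rng.integers(3))]
                stats.loc[sel, ["ref", "alt"]] = [ref, alt]

        genome = {c: a.tobytes().decode() for c, a in genome_arr.items()}
        self._genome = genome
        self._gwas = (stats, self._gwas[1])
        self.pwms = pwms
        return genome, stats

    @staticmethod
    def _write_seq(genome_arr, chrom: str, start0: int, seq: str) -> None:
        arr = genome_arr[chrom]
        if start0 < 0 or start0 + len(seq) > len(arr):
            raise ConfigError("motif does not fit inside the chromosome")
        arr[start0 : start0 + len(seq)] = np.frombuffer(
            seq.encode(), dtype="S1"
        )

    # ------------------------------------------------------------------ fragments

    def fragments(self) -> list[tuple[GenomicInterval, str, int]]:
        """Per-open-entry Tn5 insertion pairs with planted footprints.

        With ``fragment_peaks='motif'`` (default) only peaks carrying planted
        motif occurrences emit fragments, which is all that footprinting
        consumes; 'all' emits for every open entry.
        """
        cfg = self.config
        rng = self._rngs["frag"]
        bundle = self.multiome()
        if self._genome is None:
            self.sequences()
        self.truth.bias_params = {
            "amplitude": cfg.bias_amplitude,
            "period": cfg.bias_period,
            "phase": {
                chrom: float(i * 37.0)
                for i, chrom in enumerate(sorted({p.chrom for p in self.peaks}))
            },
        }
        bias = self.truth.bias_model()

        site_by_peak: dict[int, tuple[str, GenomicInterval]] = {}
        for tf, info in self.truth.footprint_sites.items():
            for j, occ in zip(info.get("peaks", []), info.get("occurrences", [])):
                site_by_peak[j] = (tf, GenomicInterval(*occ))
        if cfg.fragment_peaks == "motif":
            peak_ids = sorted(site_by_peak)
        else:
            peak_ids = list(range(len(self.peaks)))

        A = bundle.atac.tocsc()
        out: list[tuple[GenomicInterval, str, int]] = []
        a_eff = cfg.flank_boost * (1.0 - cfg.protection_factor)
        for j in peak_ids:
            peak = self.peaks[j]
            positions = np.arange(peak.start, peak.end)
            w_base = bias(peak.chrom, positions)
            tf_site = site_by_peak.get(j)
            open_cells = np.flatnonzero(np.asarray((A[:, j] > 0).todense()).ravel())
            if open_cells.size == 0:
                continue
            bound_weights = None
            if tf_site is not None:
                tf, occ = tf_site
                center = (occ.start + occ.end) // 2
                d = positions - center
                prof = 1.0 + a_eff * np.exp(-((d / cfg.flank_sigma) ** 2))
                prof = np.where(
                    np.abs(d) <= 10, prof * cfg.protection_factor, prof
                )
                bound_weights = w_base * prof
                bound_types = self.truth.footprint_sites[tf]["cell_types"]
            n_frags = rng.poisson(cfg.mean_fragments_per_open, size=open_cells.size)
            w_norm = w_base / w_base.sum()
            bw_norm = (
                bound_weights / bound_weights.sum()
                if bound_weights is not None
                else None
            )
            for ci, nf in zip(open_cells, n_frags):
                if nf == 0:
                    continue
                use_bound = (
                    bw_norm is not None
                    and self.cell_type_of[ci] in bound_types
                )
                w = bw_norm if use_bound else w_norm
                ins = rng.choice(positions, size=(int(nf), 2), p=w)
                starts = ins.min(axis=1)
                ends = ins.max(axis=1) + 1
                for s, e in zip(starts, ends):
                    out.append(
                        (GenomicInterval(peak.chrom, int(s), int(e)),
                         self.cells[ci], 1)
                    )
        out.sort(key=lambda rec: (rec[0].chrom, rec[0].start, rec[0].end, rec[1]))
        self.truth.emitted_fragments = len(out)
        return out


# ---------------------------------------------------------------------------
# stage-level convenience entry points


def generate_multiome(config: SimConfig | None = None):
    sim = Simulator(config)
    return sim.multiome(), sim.truth


def generate_gwas(config: SimConfig | None = None):
    sim = Simulator(config)
    stats, ld = sim.gwas()
    return (stats, ld), sim.truth


def generate_sequences_and_variants(config: SimConfig | None = None):
    sim = Simulator(config)
    genome, stats = sim.sequences()
    return genome, stats, sim.truth


def generate_fragments(config: SimConfig | None = None):
    sim = Simulator(config)
    frags = sim.fragments()
    return frags, sim.truth


def truth_to_jsonable(truth: SyntheticTruth) -> dict:
    d = asdict(truth)
    d["peak_patterns"] = [sorted(p) for p in truth.peak_patterns]
    d["peak_categories"] = [sorted(c) for c in truth.peak_categories]
    return d
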