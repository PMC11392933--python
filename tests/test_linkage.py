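"""Metacells, co-accessibility, modules, links, and six-level assignment."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from mga import linkage as lk
from mga.synthetic_data import SimConfig, Simulator
from mga.types import GeneModel, GenomicInterval, MultiomeBundle


def uniform_bundle(n_cells=100, n_peaks=20, fill=1):
    peaks = [GenomicInterval("chr1", 1000 * j, 1000 * j + 500) for j in range(n_peaks)]
    genes = [GeneModel("G1", "g1", "chr1", "+", 100, 600)]
    atac = sp.csr_matrix(np.full((n_cells, n_peaks), fill))
    rna = sp.csr_matrix(np.ones((n_cells, 1)))
    meta = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n_cells)],
            "sample_id": "s1",
            "cell_type": "t1",
            "category": "epithelial",
            "smoking_status": "never",
        }
    ).set_index("cell_id")
    return MultiomeBundle([f"c{i}" for i in range(n_cells)], peaks, genes, atac, rna, meta)


def island_sim(seed, n_links, **kw):
    base = dict(layout="islands", n_genes=30, n_links=n_links, island_null_peaks=1,
                cells_per_type=24, n_loci=0, n_tfs=0, marker_genes_per_type=0,
                seed=seed)
    base.update(kw)
    sim = Simulator(SimConfig(**base))
    b = sim.multiome()
    mc = lk.make_metacells(b, k=8, random_state=seed)
    ma, mr = lk.metacell_matrices(mc)
    return sim, b, ma, mr


class TestMetacells:
    def test_identical_cells_split_into_equal_groups(self):
        b = uniform_bundle(100)
        mcs = lk.make_metacells(b, k=50)
        assert len(mcs) == 2
        np.testing.assert_array_equal(mcs[0].atac, mcs[1].atac)
        assert all(len(m.members) == 50 for m in mcs)

    def test_metacell_count_is_floor_n_over_k(self, small_bundle):
        mcs = lk.make_metacells(small_bundle, k=50)
        assert len(mcs) == small_bundle.n_cells // 50
        all_members = [i for m in mcs for i in m.members]
        assert len(all_members) == len(set(all_members))

    def test_metacells_do_not_mix_well_separated_types(self, small_bundle):
        """With cell-type-patterned peaks the embedding separates categories,
        so most metacells are dominated by one category."""
        mcs = lk.make_metacells(small_bundle, k=10, random_state=0)
        meta = small_bundle.cell_meta
        cats = meta["category"].to_numpy()
        pure = 0
        for m in mcs:
            c = cats[m.members]
            pure += (pd.Series(c).value_counts().iloc[0] / len(c)) >= 0.8
        assert pure / len(mcs) >= 0.8

    def test_needs_at_least_k_cells(self):
        with pytest.raises(ValueError):
            lk.make_metacells(uniform_bundle(10), k=50)


class TestCoaccessibility:
    def test_duplicated_peak_scores_one(self, rng):
        m = rng.poisson(3, size=(40, 1)).astype(float)
        M = np.hstack([m, m, rng.poisson(3, size=(40, 1))])
        peaks = [GenomicInterval("chr1", 0, 500),
                 GenomicInterval("chr1", 1000, 1500),
                 GenomicInterval("chr1", 2000, 2500)]
        pairs = lk.coaccessibility(M, peaks)
        score01 = next(p.score for p in pairs if {p.peak_i, p.peak_j} == {0, 1})
        assert score01 == pytest.approx(1.0)

    def test_pairs_beyond_max_dist_not_reported(self, rng):
        M = rng.poisson(3, size=(40, 2)).astype(float)
        peaks = [GenomicInterval("chr1", 0, 500),
                 GenomicInterval("chr1", 900_000, 900_500)]
        assert lk.coaccessibility(M, peaks, max_dist=500_000) == []

    def test_zero_variance_peak_omitted(self, rng):
        M = np.hstack([np.full((40, 1), 5.0), rng.poisson(3, size=(40, 1))])
        peaks = [GenomicInterval("chr1", 0, 500), GenomicInterval("chr1", 1000, 1500)]
        assert lk.coaccessibility(M, peaks) == []

    def test_independent_peaks_rarely_cross_module_cutoff(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            M = (rng.random((200, 2)) < 0.5).astype(float)
            peaks = [GenomicInterval("chr1", 0, 500),
                     GenomicInterval("chr1", 1000, 1500)]
            (pair,) = lk.coaccessibility(M, peaks)
            hits += abs(pair.score) >= 0.32
        assert hits == 0  # null |r| ~ N(0, 1/sqrt(200)); 0.32 is ~4.5 sigma

    def test_coregulated_pattern_peaks_exceed_direct_cutoff(self, small_sim):
        """Two peaks planted with the same cell-type pattern co-open."""
        sim = small_sim
        b = sim.multiome()
        mcs = lk.make_metacells(b, k=10, random_state=1)
        ma, _ = lk.metacell_matrices(mcs)
        pats = {}
        for j, pat in enumerate(sim.truth.peak_patterns):
            if len(pat) == 1:
                pats.setdefault(next(iter(pat)), []).append(j)
        scores = []
        Z = (ma - ma.mean(axis=0)) / np.where(ma.std(axis=0) > 0, ma.std(axis=0), 1)
        for t, js in pats.items():
            if len(js) >= 2:
                a, bb = js[0], js[1]
                scores.append((Z[:, a] * Z[:, bb]).mean())
        assert np.median(scores) > 0.5


class TestModules:
    def pair(self, i, j, s):
        return lk.CoaccessPair(i, j, s, 1000.0)

    def test_two_disjoint_correlated_pairs_give_two_modules(self):
        pairs = [self.pair(0, 1, 0.9), self.pair(2, 3, 0.95), self.pair(0, 3, 0.1)]
        mods = lk.detect_modules(pairs)
        assert sorted(m.members for m in mods) == [(0, 1), (2, 3)]

    def test_singletons_never_form_modules(self):
        assert lk.detect_modules([self.pair(0, 1, 0.1)]) == []

    def test_three_coaccessible_ccres_share_one_module(self):
        """Three mutually co-accessible peaks resolve to a single module, the
        pattern seen at multi-CCV loci."""
        pairs = [self.pair(0, 1, 0.8), self.pair(1, 2, 0.7), self.pair(0, 2, 0.75)]
        (mod,) = lk.detect_modules(pairs)
        assert mod.members == (0, 1, 2)

    def test_seeded_louvain_is_deterministic(self, rng):
        pairs = [
            self.pair(int(i), int(j), float(s))
            for i, j, s in zip(
                rng.integers(0, 30, 200), rng.integers(0, 30, 200),
                rng.uniform(0.3, 1.0, 200),
            )
            if i != j
        ]
        a = lk.detect_modules(pairs, seed=7)
        b = lk.detect_modules(pairs, seed=7)
        assert [m.members for m in a] == [m.members for m in b]


class TestPeakGeneLinks:
    def test_zero_variance_gene_yields_no_link(self):
        b = uniform_bundle()
        mcs = lk.make_metacells(b, k=10)
        ma, mr = lk.metacell_matrices(mcs)
        links = lk.link_peaks_to_genes(ma, mr, b.peaks, b.genes,
                                       cell_atac=b.atac, cell_rna=b.rna)
        assert links == []

    def test_peak_outside_window_never_tested(self):
        sim, b, ma, mr = island_sim(1, n_links=0)
        links = lk.link_peaks_to_genes(ma, mr, b.peaks, b.genes,
                                       cell_atac=b.atac, cell_rna=b.rna,
                                       window=1_000_000)
        mids = {j: b.peaks[j].midpoint for j in range(len(b.peaks))}
        tss = {g.gene_id: g.tss for g in b.genes}
        for l in links:
            assert abs(mids[l.peak] - tss[l.gene]) <= 1_000_000

    def test_window_nesting_is_exact(self):
        sim, b, ma, mr = island_sim(2, n_links=40)
        sets = []
        for w in (1_000_000, 2_000_000, 5_000_000):
            links = lk.link_peaks_to_genes(
                ma, mr, b.peaks, b.genes, cell_atac=b.atac, cell_rna=b.rna,
                window=w,
            )
            sets.append({(l.peak, l.gene, round(l.p, 12)) for l in links})
        assert sets[0] <= sets[1] <= sets[2]

    def test_long_range_link_needs_wide_window(self):
        sim, b, ma, mr = island_sim(
            3, n_links=20, island_enhancer_dist=(3_000_000, 3_050_000),
            island_enhancers_per_gene=1,
        )
        near = lk.link_peaks_to_genes(ma, mr, b.peaks, b.genes,
                                      cell_atac=b.atac, cell_rna=b.rna,
                                      window=1_000_000)
        wide = lk.wide_window_links(ma, mr, b.peaks, b.genes,
                                    cell_atac=b.atac, cell_rna=b.rna,
                                    window=5_000_000)
        truth = {(pj, gid) for pj, gid, _ in sim.truth.links}
        assert not ({(l.peak, l.gene) for l in near} & truth)
        recovered = {(l.peak, l.gene) for l in wide} & truth
        assert len(recovered) >= 0.8 * len(truth)

    def test_planted_links_recovered(self):
        sim, b, ma, mr = island_sim(4, n_links=60)
        links = lk.link_peaks_to_genes(ma, mr, b.peaks, b.genes,
                                       cell_atac=b.atac, cell_rna=b.rna)
        truth = {(pj, gid) for pj, gid, _ in sim.truth.links}
        found = {(l.peak, l.gene) for l in links}
        assert len(truth & found) / len(truth) >= 0.8


class TestLevelAssignment:
    def test_promoter_ccre_reaches_level_three(self):
        recs = lk.assign_linkage_level(
            [5], modules=[], direct={}, promoter_genes={5: ("G1",)}, links=[]
        )
        assert [(r.gene, r.level) for r in recs] == [("G1", 3)]

    def test_isolated_ccre_yields_nothing(self):
        assert lk.assign_linkage_level([5], [], {}, {}, []) == []

    def test_matches_brute_force_on_random_instances(self, rng):
        genes = [f"G{i}" for i in range(5)]
        for _ in range(100):
            n_peaks = 20
            peaks = list(range(n_peaks))
            rng.shuffle(peaks)
            modules = []
            pool = peaks.copy()
            while len(pool) > 4 and rng.random() < 0.8:
                size = int(rng.integers(2, 5))
                members = tuple(sorted(pool[:size]))
                pool = pool[size:]
                modules.append(lk.CcreModule(len(modules), members))
            direct = {}
            for _ in range(rng.integers(0, 10)):
                i, j = rng.integers(0, n_peaks, 2)
                if i != j:
                    direct.setdefault(int(i), set()).add(int(j))
                    direct.setdefault(int(j), set()).add(int(i))
            promoter = {
                int(j): (str(rng.choice(genes)),)
                for j in rng.choice(n_peaks, rng.integers(0, 6), replace=False)
            }
            links = [
                lk.PeakGeneLink(int(j), str(rng.choice(genes)), 0.5, 3.0, 0.01, 100.0)
                for j in rng.choice(n_peaks, rng.integers(0, 6), replace=False)
            ]
            ccres = [int(c) for c in rng.choice(n_peaks, 5, replace=False)]
            got = {
                (r.peak, r.gene): r.level
                for r in lk.assign_linkage_level(ccres, modules, direct, promoter, links)
            }
            # independent re-evaluation of each predicate
            linkset = {(l.peak, l.gene) for l in links}
            expected = {}
            for c in ccres:
                mates = set()
                for m in modules:
                    if c in m.members:
                        mates = set(m.members) - {c}
                partners = direct.get(c, set())
                def bump(g, l):
                    expected[(c, g)] = max(l, expected.get((c, g), 0))
                for mate in mates:
                    for g in promoter.get(mate, ()):
                        bump(g, 1)
                    for (pk, g) in linkset:
                        if pk == mate:
                            bump(g, 4)
                for p_ in partners:
                    for g in promoter.get(p_, ()):
                        bump(g, 2)
                    for (pk, g) in linkset:
                        if pk == p_:
                            bump(g, 5)
                for g in promoter.get(c, ()):
                    bump(g, 3)
                for (pk, g) in linkset:
                    if pk == c:
                        bump(g, 6)
            assert got == expected

    def test_level6_requires_retained_link(self):
        links = [lk.PeakGeneLink(1, "G1", 0.6, 3.2, 0.004, 500.0)]
        recs = lk.assign_linkage_level([1, 2], [], {}, {}, links)
        assert {(r.peak, r.gene, r.level) for r in recs} == {(1, "G1", 6)}

    def test_most_level6_ccres_also_reach_level_4_or_5(self):
        """Redundant module/direct connections accompany most direct links."""
        sim, b, ma, mr = island_sim(6, n_links=60)
        pairs = lk.coaccessibility(ma, b.peaks)
        modules = lk.detect_modules(pairs, seed=0)
        direct = lk.direct_pairs(pairs)
        links = lk.link_peaks_to_genes(ma, mr, b.peaks, b.genes,
                                       cell_atac=b.atac, cell_rna=b.rna)
        l6_peaks = sorted({l.peak for l in links})
        recs = lk.assign_linkage_level(l6_peaks, modules, direct, {}, links)
        by_peak_gene = {}
        for r in recs:
            by_peak_gene.setdefault((r.peak, r.gene), set()).update(
                int(e[1]) for e in r.evidence
            )
        l6 = [k for k, lv in by_peak_gene.items() if 6 in lv]
        both = [k for k in l6 if by_peak_gene[k] & {4, 5}]
        assert len(both) / len(l6) > 0.5
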