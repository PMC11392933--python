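"""Detection, genomic context, and the category-specificity quantile rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mga.cre_atlas import (
    annotate_genomic_context,
    build_atlas,
    category_assignment,
    cell_type_specificity,
    detect_peaks_per_type,
    gene_activity,
    gene_activity_from_fragments,
)
from mga.types import CategoryScheme, GeneModel, GenomicInterval, ValidationError

TYPES_8744 = (
    [f"epi{i}" for i in range(1, 9)]
    + [f"imm{i}" for i in range(1, 8)]
    + [f"endo{i}" for i in range(1, 5)]
    + [f"stro{i}" for i in range(1, 5)]
)
SCHEME_8744 = CategoryScheme(
    {t: {"epi": "epithelial", "imm": "immune", "endo": "endothelial",
         "stro": "stromal"}[t.rstrip("12345678")] for t in TYPES_8744}
)


def row_from_counts(epi, imm, endo, stro):
    """Detection row with the requested per-category counts."""
    row = np.zeros(23, dtype=bool)
    row[:epi] = True
    row[8 : 8 + imm] = True
    row[15 : 15 + endo] = True
    row[19 : 19 + stro] = True
    return row


class TestCategoryAssignment:
    def test_worked_example_7_2_1_1_is_epithelial(self):
        # 7 detected epithelial types strictly exceed the 75th-percentile
        # threshold of 6 for a category of 8; no other category qualifies
        row = row_from_counts(7, 2, 1, 1)
        assert category_assignment(row, TYPES_8744, SCHEME_8744) == {"epithelial"}

    def test_single_category_detection_returns_it(self):
        row = row_from_counts(0, 3, 0, 0)
        assert category_assignment(row, TYPES_8744, SCHEME_8744) == {"immune"}

    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((7, 2, 1, 1), {"epithelial"}),
            ((6, 2, 1, 1), set()),  # 6 is not strictly above 6
            ((7, 6, 1, 1), {"epithelial", "immune"}),
            ((1, 1, 4, 1), {"endothelial"}),  # 4 > 3
            ((1, 1, 3, 1), set()),
            ((2, 2, 2, 2), set()),  # shared
        ],
    )
    def test_strict_thresholds_for_sizes_8_7_4_4(self, counts, expected):
        # strict thresholds are (6, 5.25, 3, 3): counts needed 7, 6, 4, 4
        assert category_assignment(
            row_from_counts(*counts), TYPES_8744, SCHEME_8744
        ) == expected

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(2000):
            row = rng.random(23) < rng.uniform(0.05, 0.9)
            if not row.any():
                continue
            got = category_assignment(row, TYPES_8744, SCHEME_8744)
            # independent recomputation of the quantile rule
            cats = [SCHEME_8744.mapping[t] for t, d in zip(TYPES_8744, row) if d]
            sizes = {"epithelial": 8, "immune": 7, "endothelial": 4, "stromal": 4}
            if len(set(cats)) == 1:
                expected = {cats[0]}
            else:
                expected = {
                    g for g in sizes if cats.count(g) > 0.75 * sizes[g]
                }
            assert got == expected

    def test_all_false_row_rejected(self):
        with pytest.raises(ValidationError):
            category_assignment(np.zeros(23, bool), TYPES_8744, SCHEME_8744)

    @given(st.data())
    @settings(max_examples=100, derandomize=True)
    def test_adding_detection_in_category_never_removes_it(self, data):
        row = np.array(data.draw(st.lists(st.booleans(), min_size=23, max_size=23)))
        if not row.any():
            row[0] = True
        before = category_assignment(row, TYPES_8744, SCHEME_8744)
        for g in before:
            members = [i for i, t in enumerate(TYPES_8744)
                       if SCHEME_8744.mapping[t] == g and not row[i]]
            if not members:
                continue
            row2 = row.copy()
            row2[members[0]] = True
            assert g in category_assignment(row2, TYPES_8744, SCHEME_8744)


class TestCellTypeSpecificity:
    def test_single_detection_returns_type(self):
        row = np.zeros(23, bool)
        row[3] = True
        assert cell_type_specificity(row, TYPES_8744) == "epi4"

    def test_two_detections_return_none(self):
        row = np.zeros(23, bool)
        row[[3, 10]] = True
        assert cell_type_specificity(row, TYPES_8744) is None

    def test_empty_row_rejected(self):
        with pytest.raises(ValidationError):
            cell_type_specificity(np.zeros(23, bool), TYPES_8744)


class TestDetection:
    def test_zero_cells_of_type_never_detect(self, small_bundle):
        det, types = detect_peaks_per_type(small_bundle)
        X = small_bundle.atac.tocsc()
        tarr = small_bundle.cell_meta["cell_type"].to_numpy()
        for ti, t in enumerate(types[:3]):
            col0 = np.asarray((X[tarr == t] > 0).sum(axis=0)).ravel()
            assert not det[col0 == 0, ti].any()

    def test_planted_patterns_recovered_exactly_when_noise_free(self):
        from mga.synthetic_data import SimConfig, Simulator

        sim = Simulator(
            SimConfig(cells_per_type=30, n_peaks=200, n_genes=30, p_open_low=0.0,
                      p_open_high=1.0, depth_sigma=0.0, n_loci=0, seed=2)
        )
        b = sim.multiome()
        det, types = detect_peaks_per_type(b, min_frac=0.02, min_cells=10)
        for j, pat in enumerate(sim.truth.peak_patterns):
            assert {types[t] for t in np.flatnonzero(det[j])} == set(pat)

    def test_detection_accuracy_on_default_noise(self):
        from mga.synthetic_data import SimConfig, Simulator

        sim = Simulator(
            SimConfig(cells_per_type=30, n_peaks=400, n_genes=30, n_loci=0, seed=11)
        )
        b = sim.multiome()
        det, types = detect_peaks_per_type(b)
        tindex = {t: i for i, t in enumerate(types)}
        truth = np.zeros_like(det)
        for j, pat in enumerate(sim.truth.peak_patterns):
            for t in pat:
                truth[j, tindex[t]] = True
        accuracy = (det == truth).mean()
        assert accuracy >= 0.95


class TestGenomicContext:
    GENES = [
        GeneModel("G1", "geneA", "chr1", "+", 50_000, 80_000,
                  exons=(GenomicInterval("chr1", 49_999, 50_500),
                         GenomicInterval("chr1", 60_000, 60_500))),
        GeneModel("G2", "geneB", "chr1", "-", 200_000, 150_000),
    ]

    def test_peak_on_tss_is_promoter(self):
        peak = GenomicInterval("chr1", 49_900, 50_100)
        assert annotate_genomic_context(peak, self.GENES) == "promoter"

    def test_far_peak_is_intergenic(self):
        peak = GenomicInterval("chr1", 500_000, 500_500)
        assert annotate_genomic_context(peak, self.GENES) == "intergenic"

    def test_promoter_outranks_exon(self):
        # overlaps G1's second exon AND G2's promoter window (on minus strand
        # the window is still symmetric around the TSS)
        peak = GenomicInterval("chr1", 60_100, 60_300)
        genes = self.GENES + [
            GeneModel("G3", "geneC", "chr1", "+", 61_000, 70_000)
        ]
        assert annotate_genomic_context(peak, genes) == "promoter"

    def test_gene_body_without_exon_is_intronic(self):
        peak = GenomicInterval("chr1", 70_000, 70_400)
        assert annotate_genomic_context(peak, self.GENES) == "intronic"


class TestGeneActivity:
    def test_no_signal_gives_zero(self, small_bundle):
        act = gene_activity(small_bundle)
        assert act.shape == (small_bundle.n_cells, len(small_bundle.genes))
        assert (act >= 0).all()

    def test_single_fragment_in_gene_body_counts_once(self):
        genes = [GeneModel("G1", "geneA", "chr1", "+", 1000, 5000)]
        frags = [(GenomicInterval("chr1", 2000, 2100), "c1", 1)]
        act = gene_activity_from_fragments(frags, genes, ["c1", "c2"])
        assert act[0, 0] == 1 and act[1, 0] == 0

    def test_fragment_outside_window_ignored(self):
        genes = [GeneModel("G1", "geneA", "chr1", "+", 10_000, 15_000)]
        frags = [(GenomicInterval("chr1", 100, 200), "c1", 1)]
        act = gene_activity_from_fragments(frags, genes, ["c1"])
        assert act[0, 0] == 0

    def test_marker_gene_activity_tracks_expression(self, small_bundle, small_sim):
        """Across cell types, %cells expressing a planted marker correlates
        with %cells having nonzero promoter/gene-body accessibility."""
        act = gene_activity(small_bundle)
        rna = small_bundle.rna.toarray()
        tarr = small_bundle.cell_meta["cell_type"].to_numpy()
        types = sorted(set(tarr))
        gidx = {g.gene_id: i for i, g in enumerate(small_bundle.genes)}
        rs = []
        for gene_id in list(small_sim.truth.marker_genes)[:10]:
            gi = gidx[gene_id]
            fe = [np.mean(rna[tarr == t, gi] > 0) for t in types]
            fa = [np.mean(act[tarr == t, gi] > 0) for t in types]
            if np.std(fe) > 0 and np.std(fa) > 0:
                rs.append(np.corrcoef(fe, fa)[0, 1])
        assert np.median(rs) > 0.5


class TestBuildAtlas:
    def test_atlas_consistency(self, small_bundle):
        atlas = build_atlas(small_bundle)
        assert atlas.detection.any(axis=1).all()
        for j in range(len(atlas.peaks)):
            n_det = atlas.detection[j].sum()
            if n_det == 1:
                assert atlas.specific_cell_type[j] is not None
            else:
                assert atlas.specific_cell_type[j] is None
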