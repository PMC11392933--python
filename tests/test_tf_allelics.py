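"""Motif scoring, allelic effects, abundance quantiles, and footprinting."""

import itertools

import numpy as np
import pytest

from mga.tf_allelics import (
    allelic_effect,
    footprint,
    match_p_value,
    relative_score,
    reverse_complement,
    scan_motif_occurrences,
    tf_abundance,
)
from mga.types import GenomicInterval, PWM, ValidationError, Variant


def asym_pwm(width=6, seed=0) -> PWM:
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet(np.full(4, 0.3), size=width).T
    return PWM("toy", probs)


class TestRelativeScore:
    def test_consensus_scores_exactly_one(self):
        pwm = asym_pwm()
        score, p, strand, off = relative_score(pwm, pwm.consensus)
        assert score == pytest.approx(1.0)
        assert strand == "+" and off == 0

    def test_anticonsensus_scores_exactly_zero(self):
        from mga.tf_allelics import _encode, _window_scores

        pwm = asym_pwm()
        worst = "".join("ACGT"[i] for i in pwm.probs.argmin(axis=0))
        # the forward-strand window itself hits the min-normalization floor
        (score,) = _window_scores(pwm, _encode(worst))
        assert score == pytest.approx(0.0, abs=1e-12)

    def test_strand_symmetry(self):
        pwm = asym_pwm(seed=3)
        seq = "ACGTTGCAGGTACCA"
        s_fwd, *_ = relative_score(pwm, seq)
        s_rev, *_ = relative_score(pwm, reverse_complement(seq))
        assert s_fwd == pytest.approx(s_rev)

    def test_window_with_n_is_skipped(self):
        pwm = asym_pwm(width=4)
        seq = "NN" + pwm.consensus + "NN"
        score, *_ = relative_score(pwm, seq)
        assert score == pytest.approx(1.0)

    def test_sequence_shorter_than_motif_rejected(self):
        with pytest.raises(ValidationError):
            relative_score(asym_pwm(width=6), "ACG")

    def test_match_p_equals_exhaustive_enumeration_width4(self):
        pwm = asym_pwm(width=4, seed=7)
        ic = pwm.ic
        vals = ic[None, :] * pwm.probs
        lo = (ic * pwm.probs.min(axis=0)).sum()
        hi = (ic * pwm.probs.max(axis=0)).sum()
        all_scores = []
        for word in itertools.product(range(4), repeat=4):
            raw = sum(vals[b, i] for i, b in enumerate(word))
            all_scores.append((raw - lo) / (hi - lo))
        all_scores = np.array(all_scores)
        for target in [0.2, 0.5, 0.9, 1.0]:
            expected = (all_scores >= target - 1e-12).mean()
            assert match_p_value(pwm, target) == pytest.approx(expected)

    def test_uniform_pwm_degenerates_to_p_one(self):
        pwm = PWM("flat", np.full((4, 5), 0.25))
        score, p, *_ = relative_score(pwm, "ACGTTAG")
        assert score == 0.0 and p == 1.0


class TestAllelicEffect:
    def genome_with(self, seq, chrom="chr1"):
        return {chrom: seq}

    def test_identical_alleles_rejected_by_variant_type(self):
        with pytest.raises(ValidationError):
            Variant("rs1", "chr1", 5, "A", "A")

    def test_ref_mismatch_names_position(self):
        pwm = asym_pwm()
        genome = self.genome_with("A" * 100)
        with pytest.raises(ValidationError, match="chr1:50"):
            allelic_effect(pwm, Variant("rs1", "chr1", 50, "C", "G"), genome)

    def test_delta_antisymmetric_under_allele_swap(self):
        pwm = asym_pwm(seed=5)
        base = "ACGTACGGTTCAGCATGCATGCCATGCATCAGGCATGCAGTACGGATCGATTGCACGTGCAT"
        genome = self.genome_with(base)
        v_fwd = Variant("rs1", "chr1", 30, base[29], "T" if base[29] != "T" else "G")
        pred = allelic_effect(pwm, v_fwd, genome)
        swapped = base[:29] + v_fwd.alt + base[30:]
        v_rev = Variant("rs1b", "chr1", 30, v_fwd.alt, v_fwd.ref)
        pred_rev = allelic_effect(pwm, v_rev, self.genome_with(swapped))
        assert pred.delta == pytest.approx(-pred_rev.delta)

    def test_planted_disrupting_variants_recovered(self, small_sim):
        genome, stats = small_sim.sequences()
        pwms = {p.name: p for p in small_sim.pwms}
        for vid, tf, direction in small_sim.truth.allelic_variants:
            row = stats[stats.variant_id == vid].iloc[0]
            v = Variant(vid, row.chrom, int(row.pos), row.ref, row.alt)
            pred = allelic_effect(pwms[tf], v, genome)
            assert pred.ref_score == pytest.approx(1.0)
            assert pred.delta < -0.7
            assert pred.allelic

    def test_nonplanted_variants_not_allelic(self, small_sim):
        genome, stats = small_sim.sequences()
        planted = {v for v, _, _ in small_sim.truth.allelic_variants}
        checked = flagged = 0
        for _, row in stats.iterrows():
            if row.variant_id in planted or checked >= 40:
                continue
            checked += 1
            v = Variant(row.variant_id, row.chrom, int(row.pos), row.ref, row.alt)
            for pwm in small_sim.pwms:
                flagged += allelic_effect(pwm, v, genome).allelic
        assert flagged == 0

    def test_motif_context_fixture_flags_its_tf(self):
        """A variant at the most-informative motif position, embedded in a
        heterologous promoter-like context, nominates the matching TF."""
        rng = np.random.default_rng(4)
        probs = np.full((4, 8), (1 - 0.45) / 3)
        cons = rng.integers(1, 3, size=8)  # C/G core
        probs[cons, np.arange(8)] = 0.45
        probs[:, 3] = 0.01
        probs[0, 3] = 0.97  # anchor A
        pwm = PWM("IRF8like", probs / probs.sum(axis=0))
        flank = "".join(rng.choice(list("CG"), size=30))
        site = pwm.consensus
        seq = flank + site + flank
        pos = len(flank) + 3 + 1  # 1-based anchor position
        genome = {"chr2": seq}
        pred = allelic_effect(
            pwm, Variant("rs3769823x", "chr2", pos, "A", "C"), genome
        )
        assert pred.allelic and pred.tf == "IRF8like"


class TestTfAbundance:
    def test_never_expressed_tf_not_abundant(self):
        rna = np.zeros((10, 2))
        rna[:, 1] = 5
        types = np.array(["t1"] * 10)
        res = tf_abundance(rna, ["TFa", "other"], types, {("TFa", "t1")})
        assert res[0].abundant is False and res[0].frac_expressing == 0.0

    def test_quantile_rule_on_four_pair_universe(self):
        # mean_expr ranks 1<2<3<4 across four (tf, type) pairs; only the pair
        # above the type-7 75th percentile (3.25) can be abundant
        rng = np.random.default_rng(0)
        n = 40
        rna = np.zeros((4 * n, 4))
        types = np.repeat([f"t{i}" for i in range(4)], n)
        for i, mean in enumerate([1, 2, 3, 4]):
            block = slice(i * n, (i + 1) * n)
            rna[block, i] = rng.poisson(mean * 8, n) + 1
            rna[block, (i + 1) % 4] = 1  # keep depth comparable
        universe = {(f"TF{i}", f"t{i}") for i in range(4)}
        res = tf_abundance(rna, [f"TF{i}" for i in range(4)], types, universe)
        means = {(r.tf, r.cell_type): r.mean_expr for r in res}
        cutoff = np.percentile(list(means.values()), 75)
        for r in res:
            assert r.abundant == (r.frac_expressing > 0.5 and r.mean_expr > cutoff)
        assert sum(r.abundant for r in res) == 1

    def test_planted_abundant_tf_flagged(self, small_sim, small_bundle):
        tf = "simTF1"
        bound = small_sim.tf_bound_types[tf]
        gene_names = [g.gene_name for g in small_bundle.genes]
        types = small_bundle.cell_meta["cell_type"].to_numpy()
        universe = {(tf, t) for t in small_sim.truth.cell_types}
        res = tf_abundance(small_bundle.rna, gene_names, types, universe)
        abundant_types = {r.cell_type for r in res if r.abundant}
        assert bound <= abundant_types

    def test_scale_invariance_of_flags(self):
        rng = np.random.default_rng(1)
        rna = rng.poisson(2, (60, 3)).astype(float)
        types = np.repeat(["a", "b", "c"], 20)
        uni = {("g0", t) for t in "abc"} | {("g1", t) for t in "abc"}
        base = tf_abundance(rna, ["g0", "g1", "g2"], types, uni)
        scaled = tf_abundance(rna * 7, ["g0", "g1", "g2"], types, uni)
        assert [r.abundant for r in base] == [r.abundant for r in scaled]

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            tf_abundance(np.ones((4, 1)), ["g"], np.array(["t"] * 4), set())


class TestFootprint:
    @staticmethod
    def synthetic_insertions(rng, n_sites, frac_center, n_frags, boost=0.0):
        """Fragments around site centers at x=10_000*i with optional flank boost."""
        occs, frags = [], []
        for i in range(n_sites):
            c = 10_000 * (i + 1)
            occs.append(GenomicInterval("chr1", c - 4, c + 4))
            d = np.arange(-250, 251)
            w = 1.0 + boost * np.exp(-((d / 100.0) ** 2))
            w[np.abs(d) <= 10] *= frac_center
            w = w / w.sum()
            pts = rng.choice(d, size=(n_frags, 2), p=w)
            for a, b in zip(pts.min(axis=1), pts.max(axis=1)):
                frags.append((GenomicInterval("chr1", c + a, c + b + 1), "cell", 1))
        return occs, frags

    def test_no_protection_profile_is_flat(self, rng):
        occs, frags = self.synthetic_insertions(rng, 30, 1.0, 300)
        fp = footprint(frags, occs, "t1")
        assert abs(fp.flank_enrichment) < 0.05
        assert not fp.detected

    def test_planted_protection_detected(self, rng):
        occs, frags = self.synthetic_insertions(rng, 30, 0.2, 300, boost=0.8)
        fp = footprint(frags, occs, "t1")
        assert fp.detected
        assert fp.center_depletion < fp.flank_enrichment

    def test_too_few_sites_flagged_insufficient(self, rng):
        occs, frags = self.synthetic_insertions(rng, 5, 0.2, 300, boost=0.8)
        fp = footprint(frags, occs, "t1")
        assert fp.insufficient_data and not fp.detected

    def test_whitelist_restricts_cells(self, rng):
        occs, frags = self.synthetic_insertions(rng, 25, 0.2, 200, boost=0.8)
        fp = footprint(frags, occs, "t1", cell_whitelist={"nobody"})
        assert fp.insufficient_data


class TestScanOccurrences:
    def test_planted_consensus_found(self, small_sim):
        genome, _ = small_sim.sequences()
        pwm = small_sim.pwms[0]
        info = small_sim.truth.footprint_sites[pwm.name]
        site_peaks = [small_sim.peaks[j] for j in info["peaks"]]
        occs = scan_motif_occurrences(pwm, genome, site_peaks, min_rel_score=1.0)
        found = {(o.chrom, o.start, o.end) for o in occs}
        planted = {tuple(o) for o in info["occurrences"]}
        assert planted <= found
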