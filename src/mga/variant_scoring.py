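"""CCV-cCRE colocalization, the additive 1-4 functional score, locus
summaries, and the end-to-end pipeline driver.

A CCV colocalizes with a cCRE when its 1-based position falls inside the
peak's half-open interval (s < pos <= e). Colocalized CCVs are then scored
additively over four evidence classes: (1) cCRE overlap, (2) at least one
predicted allelic-binding TF, (3) an allelic TF abundantly expressed in a
cell type where an overlapping cCRE is detected, (4) an allelic TF with a
detected footprint. Only colocalized CCVs are scored, so the minimum score
is 1 and the maximum 4.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ccv_selection import CCV, GwasLocus, ccvs_to_frame, merge_ccvs, select_ccvs
from .cre_atlas import PeakAtlas, build_atlas
from .tf_allelics import (
    AllelicPrediction,
    FootprintProfile,
    TFAbundance,
    allelic_effect,
    footprint,
    scan_motif_occurrences,
    tf_abundance,
)
from .types import GenomicInterval, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ColocalizationRecord:
    ccv: CCV
    peaks: list[int]  # bundle peak indices of overlapping cCREs
    cell_types: frozenset[str]
    categories: frozenset[str]
    single_category: str | None


@dataclass
class VariantFunctionalRecord:
    ccv: CCV
    colocalized: bool
    allelic_tfs: tuple[str, ...]
    abundance_match: bool
    footprint_match: bool
    functional_score: int


def colocalize(
    ccvs: list[CCV],
    atlas: PeakAtlas,
) -> list[ColocalizationRecord]:
    """Match CCVs to overlapping atlas cCREs with their cell-type context.

    ``single_category`` is set when the intersection of the overlapping
    peaks' category assignments resolves to exactly one category.
    """
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    src = atlas.source_indices or list(range(len(atlas.peaks)))
    for ai, p in enumerate(atlas.peaks):
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end, ai))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    known_chroms = set(by_chrom)

    out: list[ColocalizationRecord] = []
    for ccv in ccvs:
        if ccv.variant.chrom not in known_chroms:
            logger.warning(
                "CCV %s on chromosome %s absent from the atlas; skipped",
                ccv.variant.variant_id,
                ccv.variant.chrom,
            )
            continue
        hits = [
            ai
            for s, e, ai in by_chrom[ccv.variant.chrom]
            if s < ccv.variant.pos <= e
        ]
        if not hits:
            continue
        types: set[str] = set()
        cat_sets = []
        for ai in hits:
            types.update(atlas.detected_types(ai))
            cat_sets.append(set(atlas.categories[ai]))
        inter = set.intersection(*cat_sets) if cat_sets else set()
        single = next(iter(inter)) if len(inter) == 1 else None
        out.append(
            ColocalizationRecord(
                ccv=ccv,
                peaks=[src[ai] for ai in hits],
                cell_types=frozenset(types),
                categories=frozenset().union(*cat_sets),
                single_category=single,
            )
        )
    return out


def functional_score(
    record: ColocalizationRecord,
    allelic: list[AllelicPrediction],
    abundance: list[TFAbundance],
    footprints: list[FootprintProfile],
    require_type_match_abundance: bool = True,
    require_type_match_footprint: bool = False,
) -> VariantFunctionalRecord:
    """Additive 1-4 functional score for one colocalized CCV."""
    if not record.peaks:
        raise ValidationError(
            f"{record.ccv.variant.variant_id}: cannot score a non-colocalized CCV"
        )
    allelic_tfs = tuple(
        sorted({a.tf for a in allelic if a.allelic and a.variant.key == record.ccv.variant.key})
    )
    abundant_pairs = {(a.tf, a.cell_type) for a in abundance if a.abundant}
    abundance_match = any(
        tf == atf
        and (not require_type_match_abundance or ct in record.cell_types)
        for (tf, ct) in abundant_pairs
        for atf in allelic_tfs
    )
    detected_fps = {(f.tf, f.cell_type) for f in footprints if f.detected}
    footprint_match = any(
        tf == atf
        and (not require_type_match_footprint or ct in record.cell_types)
        for (tf, ct) in detected_fps
        for atf in allelic_tfs
    )
    score = (
        int(bool(record.peaks))
        + int(bool(allelic_tfs))
        + int(abundance_match)
        + int(footprint_match)
    )
    return VariantFunctionalRecord(
        ccv=record.ccv,
        colocalized=True,
        allelic_tfs=allelic_tfs,
        abundance_match=abundance_match,
        footprint_match=footprint_match,
        functional_score=score,
    )


def locus_summary(
    ccvs: list[CCV],
    colocalizations: list[ColocalizationRecord],
    scores: list[VariantFunctionalRecord],
    linkage_records: list,
) -> tuple[pd.DataFrame, dict]:
    """Per-locus evidence roll-up plus global fractions.

    A CCV shared by several loci counts in each locus row but once in the
    global unique tallies. Linkage records are attributed to every locus
    whose colocalized CCVs overlap the record's cCRE.
    """
    coloc_by_key = {c.ccv.variant.key: c for c in colocalizations}
    score_by_key = {s.ccv.variant.key: s for s in scores}
    peak_levels: dict[int, dict[str, int]] = {}
    for rec in linkage_records:
        peak_levels.setdefault(rec.peak, {})[rec.gene] = max(
            rec.level, peak_levels.get(rec.peak, {}).get(rec.gene, 0)
        )

    loci: dict[str, list[CCV]] = {}
    for c in ccvs:
        for lid in c.locus_ids:
            loci.setdefault(lid, []).append(c)

    rows = []
    for lid in sorted(loci):
        members = loci[lid]
        colocs = [coloc_by_key[c.variant.key] for c in members if c.variant.key in coloc_by_key]
        cats = sorted(set().union(*[c.categories for c in colocs])) if colocs else []
        fscores = [
            score_by_key[c.variant.key].functional_score
            for c in members
            if c.variant.key in score_by_key
        ]
        genes: dict[str, int] = {}
        for coloc in colocs:
            for pk in coloc.peaks:
                for gene, level in peak_levels.get(pk, {}).items():
                    genes[gene] = max(level, genes.get(gene, 0))
        rows.append(
            {
                "locus_id": lid,
                "n_ccvs": len(members),
                "n_colocalized": len(colocs),
                "categories": ";".join(cats),
                "max_functional_score": max(fscores) if fscores else 0,
                "n_linked_genes": len(genes),
                "n_level6_genes": sum(1 for l in genes.values() if l == 6),
                "genes_by_level": ";".join(
                    f"{g}:{l}" for g, l in sorted(genes.items())
                ),
            }
        )
    table = pd.DataFrame(rows)
    n_loci = len(loci)
    global_stats = {
        "n_loci": n_loci,
        "n_unique_ccvs": len({c.variant.key for c in ccvs}),
        "n_unique_colocalized": len({c.ccv.variant.key for c in colocalizations}),
        "frac_loci_colocalized": (
            float((table["n_colocalized"] > 0).mean()) if n_loci else 0.0
        ),
        "frac_loci_level6": (
            float((table["n_level6_genes"] > 0).mean()) if n_loci else 0.0
        ),
    }
    return table, global_stats


# ---------------------------------------------------------------------------
# end-to-end pipeline


STAGES = ("simulate", "select-ccvs", "atlas", "colocalize", "trs", "tf", "link", "score")


def run_all(
    config=None,
    out_dir: str | Path = "results",
    seed: int | None = None,
    skip: tuple[str, ...] = (),
) -> dict:
    """Run the full synthetic pipeline and write all result tables.

    ``config`` is a SimConfig (or dict of its fields); ``seed`` overrides
    the config seed. Stage names in ``skip`` are omitted along with their
    outputs; downstream stages degrade gracefully where possible.
    """
    from . import io_formats, linkage as lk, trait_relevance as tr
    from .synthetic_data import SimConfig, Simulator, truth_to_jsonable

    if config is None:
        config = SimConfig()
    elif isinstance(config, dict):
        config = SimConfig(**config)
    if seed is not None:
        config = SimConfig(**{**asdict_config(config), "seed": int(seed)})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    results: dict = {"config": config}

    def emit(name: str, df: pd.DataFrame) -> None:
        io_formats.write_table(df, out / name)
        written.append(name)

    def stage_enabled(name: str) -> bool:
        return name not in skip

    try:
        sim = Simulator(config)
        bundle = sim.multiome()
        stats, ld = sim.gwas()
        genome, stats = sim.sequences()
        fragments = sim.fragments()
        results["truth"] = sim.truth
        (out / "truth.json").write_text(
            json.dumps(truth_to_jsonable(sim.truth), sort_keys=True, default=str)
        )
        written.append("truth.json")
    except Exception as exc:
        raise RuntimeError(f"stage simulate failed: {exc}") from exc

    try:
        loci = [
            GwasLocus.from_table(lid, grp.reset_index(drop=True))
            for lid, grp in stats.merge(ld, on=["locus_id", "variant_id"]).groupby(
                "locus_id", sort=True
            )
        ]
        ccvs = merge_ccvs([select_ccvs(locus) for locus in loci])
        results["ccvs"] = ccvs
        emit("ccvs.tsv", ccvs_to_frame(ccvs))
    except Exception as exc:
        raise RuntimeError(f"stage select-ccvs failed: {exc}") from exc

    try:
        atlas = build_atlas(bundle)
        results["atlas"] = atlas
        emit("atlas.tsv", atlas.to_frame())
    except Exception as exc:
        raise RuntimeError(f"stage atlas failed: {exc}") from exc

    try:
        colocs = colocalize(ccvs, atlas)
        results["colocalizations"] = colocs
        emit(
            "colocalization.tsv",
            pd.DataFrame(
                [
                    {
                        "locus_id": c.ccv.locus_id,
                        "variant_id": c.ccv.variant.variant_id,
                        "chrom": c.ccv.variant.chrom,
                        "pos": c.ccv.variant.pos,
                        "peaks": ";".join(str(bundle.peaks[j]) for j in c.peaks),
                        "cell_types": ";".join(sorted(c.cell_types)),
                        "categories": ";".join(sorted(c.categories)),
                        "single_category": c.single_category or "",
                    }
                    for c in colocs
                ]
            ),
        )
    except Exception as exc:
        raise RuntimeError(f"stage colocalize failed: {exc}") from exc

    gc = lk.gc_fraction(genome, bundle.peaks)

    if stage_enabled("trs"):
        try:
            weights = tr.trait_weights(ccvs, bundle.peaks)
            raw_z = tr.raw_trait_score(
                bundle.atac, weights, bundle.peaks, peak_gc=gc,
                rng=config.seed,
            )
            emb = lk.tfidf_svd_embedding(bundle.atac, random_state=config.seed)
            trs, seeds, in_comp = tr.propagate_trs(
                raw_z, embedding=emb, cell_ids=bundle.cells
            )
            trs_df = pd.DataFrame(
                {
                    "cell_id": bundle.cells,
                    "raw_z": raw_z,
                    "seed": seeds,
                    "trs": trs,
                    "in_component": in_comp,
                }
            )
            results["trs"] = trs_df
            emit("trs.tsv", trs_df)
            emit(
                "trs_summary.tsv",
                tr.trs_summary(trs, bundle.cell_meta, rng=config.seed),
            )
        except Exception as exc:
            raise RuntimeError(f"stage trs failed: {exc}") from exc

    if stage_enabled("tf"):
        try:
            results.update(
                _tf_stage(sim, bundle, atlas, colocs, genome, fragments, emit)
            )
        except Exception as exc:
            raise RuntimeError(f"stage tf failed: {exc}") from exc

    if stage_enabled("link"):
        try:
            k = min(lk.DEFAULT_METACELL_K, max(5, bundle.n_cells // 20))
            metacells = lk.make_metacells(bundle, k=k, random_state=config.seed)
            m_atac, m_rna = lk.metacell_matrices(metacells)
            pairs = lk.coaccessibility(m_atac, bundle.peaks)
            modules = lk.detect_modules(pairs, seed=config.seed)
            direct = lk.direct_pairs(pairs)
            links = lk.link_peaks_to_genes(
                m_atac,
                m_rna,
                bundle.peaks,
                bundle.genes,
                cell_atac=bundle.atac,
                cell_rna=bundle.rna,
                peak_gc=gc,
            )
            src = atlas.source_indices or list(range(len(atlas.peaks)))
            promoter_map = {
                src[ai]: atlas.promoter_gene[ai]
                for ai in range(len(atlas.peaks))
                if atlas.promoter_gene[ai]
            }
            ccres = sorted({pk for c in colocs for pk in c.peaks})
            records = lk.assign_linkage_level(
                ccres, modules, direct, promoter_map, links
            )
            results["linkage_records"] = records
            emit(
                "coaccess_pairs.tsv",
                pd.DataFrame(
                    [
                        {
                            "peak_i": str(bundle.peaks[p.peak_i]),
                            "peak_j": str(bundle.peaks[p.peak_j]),
                            "score": p.score,
                            "distance": p.distance,
                        }
                        for p in pairs
                        if abs(p.score) >= lk.MODULE_CUTOFF
                    ]
                ),
            )
            emit(
                "modules.tsv",
                pd.DataFrame(
                    [
                        {
                            "module_id": m.module_id,
                            "peaks": ";".join(str(bundle.peaks[j]) for j in m.members),
                        }
                        for m in modules
                    ]
                ),
            )
            emit(
                "peak_gene_links.tsv",
                pd.DataFrame(
                    [
                        {
                            "peak": str(bundle.peaks[l.peak]),
                            "gene": l.gene,
                            "r": l.r,
                            "z": l.z,
                            "p": l.p,
                            "tss_distance": l.tss_distance,
                        }
                        for l in links
                    ]
                ),
            )
            emit(
                "linkage_records.tsv",
                pd.DataFrame(
                    [
                        {
                            "peak": str(bundle.peaks[r.peak]),
                            "gene": r.gene,
                            "level": r.level,
                            "evidence": ";".join(r.evidence),
                        }
                        for r in records
                    ]
                ),
            )
        except Exception as exc:
            raise RuntimeError(f"stage link failed: {exc}") from exc
    else:
        results["linkage_records"] = []

    try:
        allelic = results.get("allelic", [])
        abundance = results.get("abundance", [])
        footprints = results.get("footprints", [])
        scores = [
            functional_score(c, allelic, abundance, footprints) for c in colocs
        ]
        results["scores"] = scores
        emit(
            "variant_scores.tsv",
            pd.DataFrame(
                [
                    {
                        "locus_id": s.ccv.locus_id,
                        "variant_id": s.ccv.variant.variant_id,
                        "colocalized": s.colocalized,
                        "allelic_tfs": ";".join(s.allelic_tfs),
                        "abundance_match": s.abundance_match,
                        "footprint_match": s.footprint_match,
                        "functional_score": s.functional_score,
                    }
                    for s in scores
                ]
            ),
        )
        table, global_stats = locus_summary(
            ccvs, colocs, scores, results.get("linkage_records", [])
        )
        results["locus_summary"] = table
        results["global_stats"] = global_stats
        emit("locus_summary.tsv", table)
    except Exception as exc:
        raise RuntimeError(f"stage score failed: {exc}") from exc

    cfg_json = json.dumps(asdict_config(config), sort_keys=True, default=str)
    manifest = {
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "mga_version": __version__,
        "seed": config.seed,
        "skipped_stages": sorted(skip),
        "outputs": sorted(written),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    results["manifest"] = manifest
    return results


def _tf_stage(sim, bundle, atlas, colocs, genome, fragments, emit) -> dict:
    """Allelic predictions, abundance, and footprints for colocalized CCVs."""
    pwms = sim.pwms
    allelic: list[AllelicPrediction] = []
    for c in colocs:
        for pwm in pwms:
            try:
                allelic.append(allelic_effect(pwm, c.ccv.variant, genome))
            except KeyError:
                logger.warning(
                    "no sequence for %s; skipped", c.ccv.variant.variant_id
                )
    emit(
        "allelic_predictions.tsv",
        pd.DataFrame(
            [
                {
                    "variant_id": a.variant.variant_id,
                    "tf": a.tf,
                    "ref_score": a.ref_score,
                    "alt_score": a.alt_score,
                    "delta": a.delta,
                    "match_p": a.match_p,
                    "strand": a.strand,
                    "offset": a.offset,
                    "allelic": a.allelic,
                }
                for a in allelic
            ]
        ),
    )

    coloc_types: dict[tuple, set] = {}
    for c in colocs:
        coloc_types[c.ccv.variant.key] = set(c.cell_types)
    universe = {
        (a.tf, t)
        for a in allelic
        if a.allelic
        for t in coloc_types.get(a.variant.key, set())
    }
    abundance: list[TFAbundance] = []
    if universe:
        gene_names = [g.gene_name for g in bundle.genes]
        abundance = tf_abundance(
            bundle.rna,
            gene_names,
            bundle.cell_meta["cell_type"].to_numpy(),
            universe,
        )
    emit(
        "tf_abundance.tsv",
        pd.DataFrame(
            [
                {
                    "tf": a.tf,
                    "cell_type": a.cell_type,
                    "frac_expressing": a.frac_expressing,
                    "mean_expr": a.mean_expr,
                    "abundant": a.abundant,
                }
                for a in abundance
            ]
        ),
    )

    # footprints per (allelic TF, cell type): occurrences restricted to
    # peaks detected in the type; fragments pre-bucketed by cell type
    frag_by_type: dict[str, list] = {}
    type_of_cell = bundle.cell_meta["cell_type"]
    for iv, bc, count in fragments:
        frag_by_type.setdefault(type_of_cell.get(bc, "?"), []).append((iv, bc, count))
    allelic_tf_names = sorted({a.tf for a in allelic if a.allelic})
    src = atlas.source_indices or list(range(len(atlas.peaks)))
    footprints: list[FootprintProfile] = []
    for pwm in pwms:
        if pwm.name not in allelic_tf_names:
            continue
        occs_all = scan_motif_occurrences(pwm, genome, atlas.peaks, min_rel_score=1.0)
        occ_peak: list[int] = []
        for occ in occs_all:
            hit = next(
                (
                    ai
                    for ai, p in enumerate(atlas.peaks)
                    if p.chrom == occ.chrom and p.start <= occ.start and occ.end <= p.end
                ),
                None,
            )
            occ_peak.append(hit)
        for ti, cell_type in enumerate(atlas.cell_types):
            occs = [
                occ
                for occ, ai in zip(occs_all, occ_peak)
                if ai is not None and atlas.detection[ai, ti]
            ]
            fp = footprint(
                frag_by_type.get(cell_type, []),
                occs,
                cell_type,
                bias_model=sim.truth.bias_model(),
                tf=pwm.name,
            )
            footprints.append(fp)
    emit(
        "footprints.tsv",
        pd.DataFrame(
            [
                {
                    "tf": f.tf,
                    "cell_type": f.cell_type,
                    "n_sites": f.n_sites,
                    "flank_enrichment": f.flank_enrichment,
                    "center_depletion": f.center_depletion,
                    "detected": f.detected,
                    "insufficient_data": f.insufficient_data,
                }
                for f in footprints
            ]
        ),
    )
    return {"allelic": allelic, "abundance": abundance, "footprints": footprints}


def asdict_config(config) -> dict:
    from dataclasses import asdict as _asdict

    d = _asdict(config)
    d["island_enhancer_dist"] = list(d["island_enhancer_dist"])
    return d
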