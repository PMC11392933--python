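"""Candidate causal variant (CCV) selection from GWAS summary statistics.

A locus's CCV set is the lead variant, any conditional-signal leads, and
every variant either within a 1:1000 likelihood ratio of the lead or in
strong LD with it (r^2 >= 0.8 by default). The likelihood ratio between a
variant and the lead is the asymptotic normal approximation
``exp((z_var^2 - z_lead^2) / 2)``, so the inclusion rule is
``z_lead^2 - z_var^2 < 2 ln(ratio_threshold)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import ValidationError, Variant

logger = logging.getLogger(__name__)

DEFAULT_RATIO_THRESHOLD = 1000.0
DEFAULT_R2_THRESHOLD = 0.8


@dataclass
class GwasLocus:
    """One genome-wide significant locus with its variant association table.

    ``table`` columns: variant (Variant), p, z, r2_to_lead; ``lead`` must be
    one of the table's variants. ``z`` may be filled from two-sided p via the
    inverse-normal transform.
    """

    locus_id: str
    study: str
    population: str
    lead: Variant
    variants: list[Variant]
    p_values: np.ndarray
    z_scores: np.ndarray
    r2_to_lead: np.ndarray
    conditional_leads: list[Variant] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.variants)
        self.p_values = np.asarray(self.p_values, dtype=float)
        self.z_scores = np.asarray(self.z_scores, dtype=float)
        self.r2_to_lead = np.asarray(self.r2_to_lead, dtype=float)
        if not (len(self.p_values) == len(self.z_scores) == len(self.r2_to_lead) == n):
            raise ValidationError(f"{self.locus_id}: ragged variant arrays")
        if self.lead.key not in {v.key for v in self.variants}:
            raise ValidationError(f"{self.locus_id}: lead variant not in table")
        both = np.isfinite(self.p_values) & np.isfinite(self.z_scores)
        if both.any():
            implied = z_from_p(self.p_values[both])
            if not np.allclose(np.abs(self.z_scores[both]), implied, atol=1e-6):
                raise ValidationError(
                    f"{self.locus_id}: z^2 inconsistent with two-sided p"
                )

    @property
    def lead_index(self) -> int:
        keys = [v.key for v in self.variants]
        return keys.index(self.lead.key)

    @classmethod
    def from_table(
        cls,
        locus_id: str,
        df: pd.DataFrame,
        study: str = "synthetic",
        population: str = "ALL",
    ) -> "GwasLocus":
        """Build a locus from an io_formats.load_gwas_bundle per-locus frame."""
        variants = [
            Variant(str(r.variant_id), str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
            for r in df.itertuples()
        ]
        n = len(variants)
        p = df["p"].to_numpy(float) if "p" in df else np.full(n, np.nan)
        z = df["z"].to_numpy(float) if "z" in df else np.full(n, np.nan)
        r2 = (
            df["r2_to_lead"].to_numpy(float)
            if "r2_to_lead" in df
            else np.full(n, np.nan)
        )
        lead_idx = int(np.flatnonzero(df["is_lead"].astype(bool).to_numpy())[0])
        cond = []
        if "is_conditional" in df:
            cond = [
                variants[i]
                for i in np.flatnonzero(df["is_conditional"].astype(bool).to_numpy())
            ]
        pop = str(df["population"].iloc[0]) if "population" in df else population
        return cls(
            locus_id=locus_id,
            study=study,
            population=pop,
            lead=variants[lead_idx],
            variants=variants,
            p_values=p,
            z_scores=z,
            r2_to_lead=r2,
            conditional_leads=cond,
        )


@dataclass
class CCV:
    """A candidate causal variant and the evidence that included it."""

    variant: Variant
    locus_id: str
    inclusion_reason: str  # lead | conditional | llr | ld
    llr_stat: float = math.nan  # z_lead^2 - z_var^2
    r2_to_lead: float = math.nan
    locus_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.inclusion_reason not in ("lead", "conditional", "llr", "ld"):
            raise ValidationError(
                f"unknown inclusion reason {self.inclusion_reason!r}"
            )
        if not self.locus_ids:
            self.locus_ids = (self.locus_id,)


def z_from_p(p: np.ndarray | float) -> np.ndarray | float:
    """|z| implied by a two-sided normal p-value."""
    return sps.norm.isf(np.asarray(p, dtype=float) / 2.0)


def llr_include(
    z_lead: float, z_var: float, ratio_threshold: float = DEFAULT_RATIO_THRESHOLD
) -> bool:
    """Whether a variant is within a 1:ratio_threshold likelihood ratio of the lead.

    True iff exp((z_var^2 - z_lead^2)/2) >= 1/ratio_threshold, i.e.
    z_lead^2 - z_var^2 < 2 ln(ratio_threshold).
    """
    if ratio_threshold <= 1:
        raise ValueError(f"ratio_threshold must be > 1, got {ratio_threshold}")
    if not (np.isfinite(z_lead) and np.isfinite(z_var)):
        raise ValueError("llr_include requires finite z values")
    return z_lead**2 - z_var**2 < 2.0 * math.log(ratio_threshold)


def select_ccvs(
    locus: GwasLocus,
    mode: str = "llr_or_ld",
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    r2_inclusive: bool = True,
) -> list[CCV]:
    """Select the locus's CCVs under the LLR-or-LD rule (or LD only).

    The lead is always included; conditional-signal leads next; remaining
    variants qualify by the likelihood-ratio rule or by LD to the lead.
    Each variant is reported once with the strongest applicable reason
    (lead > conditional > llr > ld).
    """
    if mode not in ("llr_or_ld", "ld_only"):
        raise ValueError(f"unknown mode {mode!r}")

    z = locus.z_scores.copy()
    fill = np.isnan(z) & np.isfinite(locus.p_values)
    z[fill] = z_from_p(locus.p_values[fill])
    z = np.abs(z)
    lead_idx = locus.lead_index
    z_lead = z[lead_idx]
    cond_keys = {v.key for v in locus.conditional_leads}

    def r2_ok(r2: float) -> bool:
        if not np.isfinite(r2):
            return False
        return r2 >= r2_threshold if r2_inclusive else r2 > r2_threshold

    out: list[CCV] = []
    for i, var in enumerate(locus.variants):
        r2 = float(locus.r2_to_lead[i])
        llr_stat = (
            float(z_lead**2 - z[i] ** 2) if np.isfinite(z[i]) and np.isfinite(z_lead)
            else math.nan
        )
        if i == lead_idx:
            out.append(CCV(var, locus.locus_id, "lead", llr_stat, r2))
            continue
        if var.key in cond_keys:
            out.append(CCV(var, locus.locus_id, "conditional", llr_stat, r2))
            continue
        if mode == "llr_or_ld" and np.isfinite(z[i]) and np.isfinite(z_lead):
            if llr_include(z_lead, z[i], ratio_threshold):
                out.append(CCV(var, locus.locus_id, "llr", llr_stat, r2))
                continue
        if mode == "ld_only" and not np.isfinite(r2):
            logger.warning(
                "%s: %s has no r2 under ld_only mode; skipped",
                locus.locus_id,
                var.variant_id,
            )
            continue
        if r2_ok(r2):
            out.append(CCV(var, locus.locus_id, "ld", llr_stat, r2))
    return out


def merge_ccvs(per_study_ccvs: list[list[CCV]]) -> list[CCV]:
    """Deduplicate CCVs across studies/loci by variant identity.

    A variant appearing in several loci or studies keeps one record carrying
    all locus memberships. Two variants sharing a variant_id but disagreeing
    on alleles are a validation error.
    """
    by_key: dict[tuple, CCV] = {}
    by_id: dict[str, tuple] = {}
    order = {"lead": 0, "conditional": 1, "llr": 2, "ld": 3}
    for ccvs in per_study_ccvs:
        for ccv in ccvs:
            key = ccv.variant.key
            prev_key = by_id.get(ccv.variant.variant_id)
            if prev_key is not None and prev_key != key:
                raise ValidationError(
                    f"conflicting alleles for {ccv.variant.variant_id}: "
                    f"{prev_key} vs {key}"
                )
            by_id[ccv.variant.variant_id] = key
            if key not in by_key:
                by_key[key] = CCV(
                    ccv.variant,
                    ccv.locus_id,
                    ccv.inclusion_reason,
                    ccv.llr_stat,
                    ccv.r2_to_lead,
                    locus_ids=(ccv.locus_id,),
                )
            else:
                rec = by_key[key]
                loci = tuple(sorted(set(rec.locus_ids) | {ccv.locus_id}))
                keep = (
                    ccv
                    if order[ccv.inclusion_reason] < order[rec.inclusion_reason]
                    else rec
                )
                by_key[key] = CCV(
                    rec.variant,
                    keep.locus_id,
                    keep.inclusion_reason,
                    keep.llr_stat,
                    keep.r2_to_lead,
                    locus_ids=loci,
                )
    return sorted(
        by_key.values(), key=lambda c: (c.variant.chrom, c.variant.pos, c.variant.alt)
    )


def ccvs_to_frame(ccvs: list[CCV]) -> pd.DataFrame:
    rows = [
        {
            "locus_id": c.locus_id,
            "variant_id": c.variant.variant_id,
            "chrom": c.variant.chrom,
            "pos": c.variant.pos,
            "ref": c.variant.ref,
            "alt": c.variant.alt,
            "inclusion_reason": c.inclusion_reason,
            "llr_stat": c.llr_stat,
            "r2_to_lead": c.r2_to_lead,
            "locus_ids": ";".join(c.locus_ids),
        }
        for c in ccvs
    ]
    return pd.DataFrame(rows)
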