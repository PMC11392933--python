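"""Allelic TF-binding scores, abundant-TF calls, and Tn5 footprinting.

Motif scoring uses an information-content weighted sum: a window scores
``sum_pos ic[pos] * probs[base, pos]``, min-max normalized to [0, 1] by the
motif's worst and best attainable windows, so the consensus scores exactly 1
and the anti-consensus exactly 0. The allelic-binding call compares the
best relative score of the reference and alternate haplotype sequences; a
variant is allelic when |alt - ref| exceeds the delta threshold (0.7) and
at least one allele is a credible motif match (p <= 1e-4).

Footprints are detected from per-base Tn5 insertion frequencies aggregated
over motif occurrences, normalized to the outer flank, and corrected by
subtracting the expected insertion profile of a positional bias model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import GenomicInterval, PWM, ValidationError, Variant

logger = logging.getLogger(__name__)

DEFAULT_ALLELIC_THRESHOLD = 0.7
DEFAULT_MATCH_P_THRESHOLD = 1e-4
DEFAULT_FLANK = 30
ENUM_MAX_WIDTH = 10
MC_DRAWS = 100_000

FOOTPRINT_WINDOW = 250
FOOTPRINT_MIN_SITES = 20
THETA_FLANK = 0.05
THETA_DIP = 0.2

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class AllelicPrediction:
    variant: Variant
    tf: str
    ref_score: float
    alt_score: float
    delta: float
    match_p: float
    strand: str
    offset: int
    allelic: bool


@dataclass
class TFAbundance:
    tf: str
    cell_type: str
    frac_expressing: float
    mean_expr: float
    abundant: bool


@dataclass
class FootprintProfile:
    tf: str
    cell_type: str
    window: int
    observed: np.ndarray
    expected: np.ndarray
    corrected: np.ndarray
    flank_enrichment: float
    center_depletion: float
    detected: bool
    n_sites: int = 0
    insufficient_data: bool = False

    def __post_init__(self) -> None:
        n = 2 * self.window + 1
        for arr in (self.observed, self.expected, self.corrected):
            if len(arr) != n:
                raise ValidationError(
                    f"footprint arrays must have length {n}, got {len(arr)}"
                )


# ---------------------------------------------------------------------------
# motif scoring


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValidationError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return np.array([_BASE_INDEX.get(b, -1) for b in seq], dtype=int)


def _window_scores(pwm: PWM, encoded: np.ndarray) -> np.ndarray:
    """Relative score for every window of an encoded sequence (NaN where N)."""
    w = pwm.width
    n_win = len(encoded) - w + 1
    if n_win <= 0:
        return np.full(0, np.nan)
    ic = pwm.ic
    vals = ic[None, :] * pwm.probs  # 4 x w
    lo = float((ic * pwm.probs.min(axis=0)).sum())
    hi = float((ic * pwm.probs.max(axis=0)).sum())
    span = hi - lo
    out = np.full(n_win, np.nan)
    windows = np.lib.stride_tricks.sliding_window_view(encoded, w)
    valid = (windows >= 0).all(axis=1)
    if valid.any():
        sub = windows[valid]
        raw = vals[sub, np.arange(w)[None, :]].sum(axis=1)
        out[valid] = (raw - lo) / span if span > 0 else 0.0
    return out


def relative_score(
    pwm: PWM,
    sequence: str,
    rng: np.random.Generator | int | None = 0,
    mc_draws: int = MC_DRAWS,
) -> tuple[float, float, str, int]:
    """Best motif match in a sequence: (score in [0,1], match p, strand, offset).

    The match p-value is the probability that a random background window
    scores at least as high: exact (full enumeration over the per-position
    score distribution) for widths <= 10, seeded Monte Carlo otherwise.
    Offsets index the forward strand; windows containing N are skipped.
    """
    if len(sequence) < pwm.width:
        raise ValidationError(
            f"sequence length {len(sequence)} < motif width {pwm.width}"
        )
    fwd = _window_scores(pwm, _encode(sequence))
    rev = _window_scores(pwm, _encode(reverse_complement(sequence)))
    best_score, best_strand, best_offset = -np.inf, "+", 0
    if np.isfinite(fwd).any():
        i = int(np.nanargmax(fwd))
        best_score, best_strand, best_offset = float(fwd[i]), "+", i
    if np.isfinite(rev).any():
        i = int(np.nanargmax(rev))
        if float(rev[i]) > best_score:
            # map the reverse-strand window back to forward coordinates
            best_score = float(rev[i])
            best_strand = "-"
            best_offset = len(sequence) - pwm.width - i
    if not np.isfinite(best_score):
        return 0.0, 1.0, "+", 0
    p = match_p_value(pwm, best_score, rng=rng, mc_draws=mc_draws)
    return best_score, p, best_strand, best_offset


def match_p_value(
    pwm: PWM,
    score: float,
    rng: np.random.Generator | int | None = 0,
    mc_draws: int = MC_DRAWS,
) -> float:
    """P(random background window relative score >= score)."""
    ic = pwm.ic
    vals = ic[None, :] * pwm.probs
    lo = float((ic * pwm.probs.min(axis=0)).sum())
    hi = float((ic * pwm.probs.max(axis=0)).sum())
    span = hi - lo
    if span <= 0:
        return 1.0
    # relative score of a window = (sum_pos vals[base, pos] - lo) / span
    if pwm.width <= ENUM_MAX_WIDTH:
        scores = np.zeros(1)
        probs = np.ones(1)
        for pos in range(pwm.width):
            scores = (scores[:, None] + vals[:, pos][None, :]).ravel()
            probs = (probs[:, None] * pwm.background[None, :]).ravel()
        rel = (scores - lo) / span
        return float(probs[rel >= score - 1e-12].sum())
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    draws = gen.choice(4, size=(mc_draws, pwm.width), p=pwm.background / pwm.background.sum())
    raw = vals[draws, np.arange(pwm.width)[None, :]].sum(axis=1)
    rel = (raw - lo) / span
    return float((rel >= score - 1e-12).mean())


# ---------------------------------------------------------------------------
# allelic effects


def _fetch(genome, chrom: str, start0: int, end0: int) -> str:
    """Fetch [start0, end0) uppercase sequence from a dict or pyfaidx.Fasta."""
    if isinstance(genome, dict):
        seq = genome[chrom][max(0, start0) : end0]
    else:  # pyfaidx.Fasta-like
        seq = str(genome[chrom][max(0, start0) : end0])
    return seq.upper()


def allelic_effect(
    pwm: PWM,
    variant: Variant,
    genome,
    flank: int = DEFAULT_FLANK,
    allelic_threshold: float = DEFAULT_ALLELIC_THRESHOLD,
    p_threshold: float = DEFAULT_MATCH_P_THRESHOLD,
    rng: np.random.Generator | int | None = 0,
) -> AllelicPrediction:
    """Score the reference and alternate haplotypes around a variant.

    The reference window is the variant's ref allele +/- ``flank`` bp; the
    alternate substitutes the alt allele (length changes allowed). The
    variant is flagged allelic when |delta| exceeds the threshold and the
    better allele is a credible motif match.
    """
    start0 = variant.pos - 1 - flank
    end0 = variant.pos - 1 + len(variant.ref) + flank
    seq = _fetch(genome, variant.chrom, start0, end0)
    left_pad = (variant.pos - 1) - max(0, start0)
    observed_ref = seq[left_pad : left_pad + len(variant.ref)]
    if observed_ref != variant.ref:
        raise ValidationError(
            f"{variant.variant_id}: genome has {observed_ref!r} at "
            f"{variant.chrom}:{variant.pos}, expected ref {variant.ref!r}"
        )
    ref_seq = seq
    alt_seq = seq[:left_pad] + variant.alt + seq[left_pad + len(variant.ref) :]
    # only motif placements covering the variant are compared (the same
    # contract motif-disruption tools use)
    ref_score, ref_p, ref_strand, ref_off = _best_overlapping(
        pwm, ref_seq, left_pad, left_pad + len(variant.ref), rng
    )
    alt_score, alt_p, alt_strand, alt_off = _best_overlapping(
        pwm, alt_seq, left_pad, left_pad + len(variant.alt), rng
    )
    delta = alt_score - ref_score
    if ref_score >= alt_score:
        strand, offset = ref_strand, ref_off - left_pad
    else:
        strand, offset = alt_strand, alt_off - left_pad
    match_p = min(ref_p, alt_p)
    allelic = abs(delta) > allelic_threshold and match_p <= p_threshold
    return AllelicPrediction(
        variant=variant,
        tf=pwm.name,
        ref_score=ref_score,
        alt_score=alt_score,
        delta=delta,
        match_p=match_p,
        strand=strand,
        offset=offset,
        allelic=allelic,
    )


def _best_overlapping(
    pwm: PWM, seq: str, lo: int, hi: int, rng
) -> tuple[float, float, str, int]:
    """Best relative score among windows overlapping [lo, hi) on either strand."""
    w = pwm.width
    fwd = _window_scores(pwm, _encode(seq))
    rev = _window_scores(pwm, _encode(reverse_complement(seq)))
    best = (-np.inf, "+", 0)
    for i, s in enumerate(fwd):
        if np.isfinite(s) and i < hi and i + w > lo and s > best[0]:
            best = (float(s), "+", i)
    n = len(seq)
    for i, s in enumerate(rev):
        j = n - w - i  # forward-strand start of this reverse window
        if np.isfinite(s) and j < hi and j + w > lo and s > best[0]:
            best = (float(s), "-", j)
    if not np.isfinite(best[0]):
        return 0.0, 1.0, "+", 0
    p = match_p_value(pwm, best[0], rng=rng)
    return best[0], p, best[1], best[2]


# ---------------------------------------------------------------------------
# TF abundance


def tf_abundance(
    rna,
    gene_names: list[str],
    cell_types_per_cell: np.ndarray | pd.Series,
    prediction_universe: set[tuple[str, str]],
    frac_threshold: float = 0.5,
    percentile: float = 75.0,
    target_sum: float = 1e4,
) -> list[TFAbundance]:
    """Flag abundant TFs per cell type over a prediction universe.

    A (TF, cell type) pair is abundant when the TF is expressed in more than
    ``frac_threshold`` of the type's cells and its mean log-normalized
    expression exceeds the ``percentile``-th percentile (linear-interpolation
    quantile) of mean expression over all pairs in the universe.
    """
    if not prediction_universe:
        raise ValidationError("prediction universe is empty")
    import scipy.sparse as sp

    X = rna.tocsr() if sp.issparse(rna) else np.asarray(rna)
    depth = np.asarray(X.sum(axis=1)).ravel().astype(float)
    depth[depth == 0] = 1.0
    gene_idx = {g: i for i, g in enumerate(gene_names)}
    ct = np.asarray(cell_types_per_cell)
    types = sorted(set(ct))

    stats: dict[tuple[str, str], tuple[float, float]] = {}
    tfs = sorted({tf for tf, _ in prediction_universe})
    for tf in tfs:
        gi = gene_idx.get(tf)
        if gi is None:
            logger.warning("TF %s absent from expression matrix", tf)
        for t in types:
            if (tf, t) not in prediction_universe:
                continue
            if gi is None:
                stats[(tf, t)] = (0.0, 0.0)
                continue
            mask = ct == t
            col = X[mask, gi]
            col = np.asarray(col.todense()).ravel() if sp.issparse(col) else np.ravel(col)
            frac = float((col > 0).mean()) if mask.any() else 0.0
            norm = np.log1p(col / depth[mask] * target_sum)
            stats[(tf, t)] = (frac, float(norm.mean()) if mask.any() else 0.0)

    means = np.array([m for _, m in stats.values()])
    cutoff = float(np.percentile(means, percentile)) if len(means) else np.inf
    out = []
    for (tf, t), (frac, mean) in sorted(stats.items()):
        out.append(
            TFAbundance(
                tf=tf,
                cell_type=t,
                frac_expressing=frac,
                mean_expr=mean,
                abundant=(frac > frac_threshold and mean > cutoff),
            )
        )
    return out


# ---------------------------------------------------------------------------
# footprinting


def footprint(
    fragments,
    motif_occurrences: list[GenomicInterval],
    cell_type: str,
    cell_whitelist: set[str] | None = None,
    bias_model=None,
    tf: str = "",
    window: int = FOOTPRINT_WINDOW,
    min_sites: int = FOOTPRINT_MIN_SITES,
    theta_flank: float = THETA_FLANK,
    theta_dip: float = THETA_DIP,
) -> FootprintProfile:
    """Aggregate bias-corrected Tn5 insertion profile around motif occurrences.

    ``fragments`` is an iterable of (GenomicInterval, barcode, count); both
    fragment ends count as insertions. ``bias_model`` maps (chrom, positions
    array) to positional bias multipliers; when None the expected profile is
    flat. Frequencies are normalized to mean 1 over the outer flank
    (200 <= |d| <= 250 at the default window).
    """
    n = 2 * window + 1
    observed = np.zeros(n)
    centers_by_chrom: dict[str, np.ndarray] = {}
    for occ in motif_occurrences:
        centers_by_chrom.setdefault(occ.chrom, [])
    for occ in motif_occurrences:
        centers_by_chrom[occ.chrom].append((occ.start + occ.end) // 2)
    centers_by_chrom = {
        c: np.asarray(sorted(v)) for c, v in centers_by_chrom.items()
    }
    n_sites = len(motif_occurrences)

    for iv, bc, count in fragments:
        if cell_whitelist is not None and bc not in cell_whitelist:
            continue
        centers = centers_by_chrom.get(iv.chrom)
        if centers is None or centers.size == 0:
            continue
        for ins in (iv.start, iv.end - 1):
            lo = np.searchsorted(centers, ins - window)
            hi = np.searchsorted(centers, ins + window, side="right")
            for c in centers[lo:hi]:
                d = ins - c
                if -window <= d <= window:
                    observed[d + window] += count

    d = np.arange(-window, window + 1)
    outer = (np.abs(d) >= int(0.8 * window)) & (np.abs(d) <= window)
    flank_band = (np.abs(d) >= 20) & (np.abs(d) <= 100)
    center_band = np.abs(d) <= 10

    insufficient = n_sites < min_sites or observed[outer].mean() <= 0
    if observed[outer].mean() > 0:
        obs_norm = observed / observed[outer].mean()
    else:
        obs_norm = np.zeros(n)

    if bias_model is None:
        expected = np.ones(n)
    else:
        expected = np.zeros(n)
        total = 0
        for chrom, centers in centers_by_chrom.items():
            for c in centers:
                expected += np.asarray(bias_model(chrom, c + d), dtype=float)
                total += 1
        expected = expected / max(total, 1)
        if expected[outer].mean() > 0:
            expected = expected / expected[outer].mean()

    corrected = obs_norm - expected
    flank_enrichment = float(corrected[flank_band].mean())
    center_depletion = float(corrected[center_band].mean())
    detected = (
        not insufficient
        and flank_enrichment >= theta_flank
        and center_depletion <= flank_enrichment * (1 - theta_dip)
    )
    return FootprintProfile(
        tf=tf,
        cell_type=cell_type,
        window=window,
        observed=obs_norm,
        expected=expected,
        corrected=corrected,
        flank_enrichment=flank_enrichment,
        center_depletion=center_depletion,
        detected=detected,
        n_sites=n_sites,
        insufficient_data=insufficient,
    )


def scan_motif_occurrences(
    pwm: PWM,
    genome,
    peaks: list[GenomicInterval],
    min_rel_score: float = 0.85,
) -> list[GenomicInterval]:
    """Non-overlapping motif matches (relative score >= threshold) within peaks."""
    occurrences: list[GenomicInterval] = []
    for peak in peaks:
        seq = _fetch(genome, peak.chrom, peak.start, peak.end)
        if len(seq) < pwm.width:
            continue
        scores = _window_scores(pwm, _encode(seq))
        rev = _window_scores(pwm, _encode(reverse_complement(seq)))
        if np.isfinite(rev).any():
            rev_fwd = rev[::-1]  # reverse window i starts at len-w-i on forward
            scores = np.fmax(scores, rev_fwd)
        order = np.argsort(scores)[::-1]
        taken: list[tuple[int, int]] = []
        for i in order:
            s = scores[i]
            if not np.isfinite(s) or s < min_rel_score:
                break
            a, b = peak.start + i, peak.start + i + pwm.width
            if all(b <= ta or a >= tb for ta, tb in taken):
                taken.append((a, b))
        occurrences.extend(GenomicInterval(peak.chrom, a, b) for a, b in sorted(taken))
    return occurrences
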