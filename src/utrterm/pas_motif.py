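"""Polyadenylation-signal hexamer scanning and crosslink-terminus geometry.

The canonical PAS hexamer is AAUAAA; a configurable extended set (e.g.
AUUAAA) is supported.  T and U are equivalent, N never matches, and
overlapping occurrences are all reported.  Positional enrichment of PAS
near peaks is assessed against a within-UTR shuffle null that preserves
each peak's width and its UTR (so sequence composition is controlled):
each shuffle re-draws every peak's start uniformly within its own UTR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .formats_io import GenomeInterval
from .transcript_model import TranscriptAnnotation

CANONICAL_PAS = ("AAUAAA",)
EXTENDED_PAS = ("AAUAAA", "AUUAAA")


def _normalize(seq: str) -> str:
    return seq.upper().replace("T", "U")


def find_pas(sequence: str, motifs: Sequence[str] = CANONICAL_PAS) -> list[int]:
    """All 0-based start positions of any motif (overlaps included)."""
    seq = _normalize(sequence)
    positions: set[int] = set()
    for motif in motifs:
        m = _normalize(motif)
        if len(m) != 6:
            raise ValueError(f"PAS motif must be a 6-mer, got {motif!r}")
        start = seq.find(m)
        while start != -1:
            positions.add(start)
            start = seq.find(m, start + 1)
    return sorted(positions)


def utr3_local_interval(peak: GenomeInterval, utr: TranscriptAnnotation) -> tuple[int, int]:
    """Map a genomic peak inside a 3'-UTR to UTR-local (5'->3') coordinates."""
    iv = utr.utr3_interval
    if iv is None:
        raise ValueError(f"{utr.transcript_id} has no 3'-UTR interval")
    if peak.chrom != iv.chrom or peak.start < iv.start or peak.end > iv.end:
        raise ValueError(
            f"peak {peak.chrom}:{peak.start}-{peak.end} outside 3'-UTR of "
            f"{utr.transcript_id}"
        )
    if iv.strand == "+":
        return peak.start - iv.start, peak.end - iv.start
    return iv.end - peak.end, iv.end - peak.start


@dataclass
class PasEnrichmentResult:
    observed_fraction: float
    null_fractions: list[float]
    empirical_p: float
    window: int
    n_peaks: int
    n_skipped: int = 0
    motifs: tuple = CANONICAL_PAS


def peak_pas_fraction(
    assigned_peaks: Iterable[tuple[GenomeInterval, TranscriptAnnotation]],
    flank: int = 25,
    motifs: Sequence[str] = CANONICAL_PAS,
) -> tuple[float, int]:
    """Fraction of peaks whose flanked window contains a PAS hit.

    The window is [start - flank, end + flank) in UTR-local coordinates,
    clipped to the UTR.  Peaks on UTRs without sequence are excluded and
    counted in the returned n_excluded.
    """
    n_hit = n_used = n_excluded = 0
    hit_cache: dict[str, np.ndarray] = {}
    for peak, utr in assigned_peaks:
        seq = utr.utr3_sequence
        if seq is None:
            n_excluded += 1
            continue
        s, e = utr3_local_interval(peak, utr)
        hits = hit_cache.get(utr.transcript_id)
        if hits is None:
            hits = np.asarray(find_pas(seq, motifs), dtype=np.int64)
            hit_cache[utr.transcript_id] = hits
        lo, hi = max(0, s - flank), min(len(seq), e + flank)
        n_used += 1
        if np.searchsorted(hits, hi) > np.searchsorted(hits, lo):
            n_hit += 1
    if n_used == 0:
        raise ValueError("no peaks with sequence available")
    return n_hit / n_used, n_excluded


def pas_positional_enrichment(
    assigned_peaks: Sequence[tuple[GenomeInterval, TranscriptAnnotation]],
    flank: int = 25,
    n_shuffles: int = 1000,
    seed: int = 0,
    motifs: Sequence[str] = CANONICAL_PAS,
) -> PasEnrichmentResult:
    """Empirical PAS-proximity enrichment against the within-UTR shuffle null.

    empirical_p = (1 + #{null fraction >= observed}) / (n_shuffles + 1);
    deterministic given the seed.  Peaks wider than their UTR are skipped
    and reported.
    """
    if n_shuffles < 100:
        raise ValueError(f"n_shuffles must be >= 100, got {n_shuffles}")
    rng = np.random.default_rng(seed)
    hit_cache: dict[str, np.ndarray] = {}
    widths, utr_lens, hit_arrays, observed_flags = [], [], [], []
    n_skipped = 0
    for peak, utr in assigned_peaks:
        seq = utr.utr3_sequence
        if seq is None:
            n_skipped += 1
            continue
        s, e = utr3_local_interval(peak, utr)
        w = e - s
        if w > len(seq):
            n_skipped += 1
            continue
        hits = hit_cache.get(utr.transcript_id)
        if hits is None:
            hits = np.asarray(find_pas(seq, motifs), dtype=np.int64)
            hit_cache[utr.transcript_id] = hits
        lo, hi = max(0, s - flank), min(len(seq), e + flank)
        observed_flags.append(
            np.searchsorted(hits, hi) > np.searchsorted(hits, lo)
        )
        widths.append(w)
        utr_lens.append(len(seq))
        hit_arrays.append(hits)
    n_peaks = len(widths)
    if n_peaks == 0:
        raise ValueError("no usable peaks for enrichment")
    observed = float(np.mean(observed_flags))
    widths_a = np.asarray(widths)
    utr_lens_a = np.asarray(utr_lens)
    span = utr_lens_a - widths_a + 1  # admissible start count per peak
    # precompute, per peak, whether a window at each admissible start has a
    # hit; shuffles then become one vectorized gather per draw
    ok_chunks = []
    for j in range(n_peaks):
        s_all = np.arange(span[j])
        lo = np.maximum(0, s_all - flank)
        hi = np.minimum(utr_lens_a[j], s_all + widths_a[j] + flank)
        h = hit_arrays[j]
        ok_chunks.append(np.searchsorted(h, hi) > np.searchsorted(h, lo))
    offsets = np.concatenate(([0], np.cumsum(span)))[:-1]
    ok_flat = np.concatenate(ok_chunks)
    null_fractions = np.empty(n_shuffles)
    for i in range(n_shuffles):
        starts = rng.integers(0, span)  # uniform over [0, utr_len - width]
        null_fractions[i] = ok_flat[offsets + starts].mean()
    empirical_p = (1 + int(np.sum(null_fractions >= observed))) / (n_shuffles + 1)
    return PasEnrichmentResult(
        observed_fraction=observed,
        null_fractions=null_fractions.tolist(),
        empirical_p=empirical_p,
        window=flank,
        n_peaks=n_peaks,
        n_skipped=n_skipped,
        motifs=tuple(motifs),
    )


def terminal_distance_distribution(
    assigned_peaks: Iterable[tuple[GenomeInterval, TranscriptAnnotation]],
) -> np.ndarray:
    """Distance (nt) from each peak's 3' edge to its UTR's 3' terminus.

    Strand-aware: on '+' the terminus is utr3_interval.end, on '-' it is
    utr3_interval.start.  A peak outside its UTR raises, naming the peak.
    """
    distances = []
    for peak, utr in assigned_peaks:
        iv = utr.utr3_interval
        if iv is None or not (
            peak.chrom == iv.chrom and peak.start >= iv.start and peak.end <= iv.end
        ):
            raise ValueError(
                f"peak {peak.chrom}:{peak.start}-{peak.end} outside 3'-UTR of "
                f"{utr.transcript_id}"
            )
        if iv.strand == "+":
            distances.append(iv.end - peak.end)
        else:
            distances.append(peak.start - iv.start)
    return np.asarray(distances, dtype=np.int64)
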