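"""Colocalization statistics for CLIP and APA peak presence in 3'-UTRs.

The central quantity is a 2x2 contingency table over the analysis set of
non-overlapping expressed 3'-UTRs: each UTR either carries (>= 1
overlapping base) or lacks a reproducible peak from each assay.  The
association is summarized by the sample odds ratio ad/bc and Fisher's
exact test, computed here with exact integer arithmetic: hypergeometric
table weights are big-integer binomial products, two-sided tie comparison
is an integer comparison, and the p-value is an exact rational rounded to
float at the very end.  No continuity correction is applied to the odds
ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .formats_io import GenomeInterval
from .peaklib import ReplicatePeakSet, reproducible_peaks
from .transcript_model import TranscriptAnnotation


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of analysis UTRs: a = both assays, b = APA only, c = CLIP only,
    d = neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    def transpose(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.a, self.c, self.b, self.d)


@dataclass
class AssociationResult:
    odds_ratio: float
    p_value: float
    table: ContingencyTable2x2
    alternative: str = "two-sided"


def _interval_index(peaks: Sequence[GenomeInterval]):
    """Per-chromosome sorted starts plus running-max ends, for overlap queries."""
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    grouped: dict[str, list[tuple[int, int]]] = {}
    for iv in peaks:
        grouped.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom, ivs in grouped.items():
        ivs.sort()
        starts = np.asarray([s for s, _ in ivs], dtype=np.int64)
        ends = np.asarray([e for _, e in ivs], dtype=np.int64)
        by_chrom[chrom] = (starts, np.maximum.accumulate(ends))
    return by_chrom


def _has_overlap(index, iv: GenomeInterval) -> bool:
    entry = index.get(iv.chrom)
    if entry is None:
        return False
    starts, maxends = entry
    k = int(np.searchsorted(starts, iv.end, side="left"))
    return k > 0 and int(maxends[k - 1]) > iv.start


def build_contingency(
    utrs: Sequence[TranscriptAnnotation],
    apa_peaks: Sequence[GenomeInterval],
    clip_peaks: Sequence[GenomeInterval],
) -> ContingencyTable2x2:
    """Tally UTRs by presence of reproducible APA/CLIP peaks.

    A UTR "has" a peak iff at least one base of a peak lies within its
    3'-UTR genomic interval (half-open; a peak abutting the UTR end does
    not overlap).
    """
    apa_idx = _interval_index(apa_peaks)
    clip_idx = _interval_index(clip_peaks)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for utr in utrs:
        iv = utr.utr3_interval
        if iv is None:
            raise ValueError(f"{utr.transcript_id} has no 3'-UTR interval")
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    a = b = c = d = 0
    for chrom, ivs in by_chrom.items():
        u_start = np.asarray([s for s, _ in ivs], dtype=np.int64)
        u_end = np.asarray([e for _, e in ivs], dtype=np.int64)

        def presence(index) -> np.ndarray:
            entry = index.get(chrom)
            if entry is None:
                return np.zeros(u_start.size, dtype=bool)
            starts, maxends = entry
            k = np.searchsorted(starts, u_end, side="left")
            has = k > 0
            has[has] = maxends[k[has] - 1] > u_start[has]
            return has

        has_apa = presence(apa_idx)
        has_clip = presence(clip_idx)
        a += int(np.sum(has_apa & has_clip))
        b += int(np.sum(has_apa & ~has_clip))
        c += int(np.sum(~has_apa & has_clip))
        d += int(np.sum(~has_apa & ~has_clip))
    return ContingencyTable2x2(a, b, c, d)


def odds_ratio(table: ContingencyTable2x2) -> float:
    """Sample odds ratio ad/bc.

    +inf when bc = 0 with ad > 0; NaN (undefined) when both products are 0.
    """
    ad = table.a * table.d
    bc = table.b * table.c
    if bc == 0:
        return float("inf") if ad > 0 else float("nan")
    return ad / bc


def fisher_exact(table: ContingencyTable2x2, alternative: str = "two-sided") -> float:
    """Fisher's exact test on a 2x2 table, margins fixed.

    The number of "both" UTRs follows the hypergeometric distribution over
    tables with the observed margins.  Two-sided p sums the probabilities
    of all tables whose point probability does not exceed the observed one;
    because weights are exact integers the tie comparison is exact.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    a, b, c, d = table.as_tuple()
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1 = a + b
    col1 = a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    weights = [
        math.comb(row1, x) * math.comb(n - row1, col1 - x) for x in range(lo, hi + 1)
    ]
    total = math.comb(n, col1)
    w_obs = weights[a - lo]
    if alternative == "two-sided":
        selected = sum(w for w in weights if w <= w_obs)
    elif alternative == "greater":
        selected = sum(weights[a - lo :])
    else:
        selected = sum(weights[: a - lo + 1])
    p = Fraction(selected, total)
    return min(1.0, float(p))


def associate(
    utrs: Sequence[TranscriptAnnotation],
    apa_repset: ReplicatePeakSet,
    clip_repset: ReplicatePeakSet,
    alternative: str = "two-sided",
) -> AssociationResult:
    """Reproducible peaks per assay -> contingency table -> OR + exact p."""
    apa = reproducible_peaks(apa_repset)
    clip = reproducible_peaks(clip_repset)
    table = build_contingency(utrs, apa, clip)
    return AssociationResult(
        odds_ratio=odds_ratio(table),
        p_value=fisher_exact(table, alternative=alternative),
        table=table,
        alternative=alternative,
    )


def signal_vs_utr3_length(
    per_utr_terminal_signal: Iterable[float], utr3_lengths: Iterable[float]
) -> dict:
    """Spearman correlation of terminal-window signal against 3'-UTR length.

    Used as an independence check: a terminus-scanning mechanism would put
    more signal on short UTRs, i.e. a negative correlation.  A constant
    vector leaves the correlation undefined (NaN).
    """
    x = np.asarray(list(per_utr_terminal_signal), dtype=float)
    y = np.asarray(list(utr3_lengths), dtype=float)
    if x.size != y.size:
        raise ValueError("paired vectors required")
    if x.size < 3:
        raise ValueError(f"need n >= 3 pairs, got {x.size}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return {"rho": float("nan"), "n": int(x.size)}
    rho = stats.spearmanr(x, y).statistic
    return {"rho": float(rho), "n": int(x.size)}
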