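"""Replicate-reproducible peak derivation and coverage normalization.

Reproducibility is defined at base resolution: a genomic base is
reproducible when it is covered by at least one peak in *every* replicate,
and reproducible peaks are the maximal contiguous runs of such bases.
This is deterministic, order-independent, and equivalent to the
intersect-then-merge idiom of interval toolkits.  Peak scores are not
propagated: downstream statistics are presence/absence based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formats_io import GenomeInterval, Peak


@dataclass
class ReplicatePeakSet:
    """Peak lists from n >= 1 biological replicates of one assay."""

    assay: str
    replicates: list[list[Peak]]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError("need at least one replicate")
        if not self.labels:
            self.labels = [f"rep{i + 1}" for i in range(len(self.replicates))]
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("replicate labels must be unique")
        if len(self.labels) != len(self.replicates):
            raise ValueError("labels/replicates length mismatch")


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping-or-touching [start, end) intervals (sorted output)."""
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    # a new run begins where start exceeds the running max end so far
    run_max = np.maximum.accumulate(ends)
    new_run = np.concatenate(([True], starts[1:] > run_max[:-1]))
    run_id = np.cumsum(new_run) - 1
    merged_starts = starts[new_run]
    merged_ends = np.maximum.reduceat(ends, np.flatnonzero(new_run))
    del run_id
    return merged_starts, merged_ends


def reproducible_intervals_arrays(
    replicate_intervals: Sequence[tuple[np.ndarray, np.ndarray]],
) -> tuple[np.ndarray, np.ndarray]:
    """Base-level intersection of replicate interval sets on one chromosome.

    Each replicate is a (starts, ends) pair.  Returns the maximal runs of
    bases covered in every replicate.
    """
    n = len(replicate_intervals)
    events = []
    for starts, ends in replicate_intervals:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if starts.size == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        ms, me = merge_intervals(starts, ends)  # per-replicate depth now 0/1
        events.append((ms, me))
    pos = np.concatenate([np.concatenate((s, e)) for s, e in events])
    delta = np.concatenate(
        [np.concatenate((np.ones(s.size, np.int64), -np.ones(e.size, np.int64)))
         for s, e in events]
    )
    order = np.argsort(pos, kind="stable")
    pos, delta = pos[order], delta[order]
    # collapse equal positions, then scan depth
    uniq, idx = np.unique(pos, return_index=True)
    depth_change = np.add.reduceat(delta, idx)
    depth = np.cumsum(depth_change)
    covered = depth == n  # depth in [uniq[i], uniq[i+1])
    starts_out, ends_out = [], []
    for i in np.flatnonzero(covered):
        if i + 1 < uniq.size:
            s, e = uniq[i], uniq[i + 1]
            if starts_out and s == ends_out[-1]:
                ends_out[-1] = e
            else:
                starts_out.append(s)
                ends_out.append(e)
    return np.asarray(starts_out, dtype=np.int64), np.asarray(ends_out, dtype=np.int64)


def reproducible_peaks(peakset: ReplicatePeakSet) -> list[GenomeInterval]:
    """Maximal runs of bases covered by >=1 peak in every replicate.

    With a single replicate this reduces to merging its peaks.  The output
    never overlaps itself, and adding a replicate can only shrink or
    preserve the reproducible base set.
    """
    chroms: dict[str, list[tuple[list[int], list[int]]]] = {}
    n = len(peakset.replicates)
    for ri, peaks in enumerate(peakset.replicates):
        for p in peaks:
            per_chrom = chroms.setdefault(
                p.interval.chrom, [([], []) for _ in range(n)]
            )
            per_chrom[ri][0].append(p.interval.start)
            per_chrom[ri][1].append(p.interval.end)
    out: list[GenomeInterval] = []
    for chrom in sorted(chroms):
        reps = [
            (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
            for s, e in chroms[chrom]
        ]
        starts, ends = reproducible_intervals_arrays(reps)
        out.extend(GenomeInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return out


def cpm_normalize(
    raw_coverage: Mapping[str, np.ndarray] | np.ndarray, library_size: float
):
    """Counts-per-million scaling: value * 1e6 / library_size."""
    if library_size <= 0:
        raise ValueError(f"library_size must be positive, got {library_size}")
    factor = 1e6 / library_size
    if isinstance(raw_coverage, Mapping):
        return {c: np.asarray(v, dtype=float) * factor for c, v in raw_coverage.items()}
    return np.asarray(raw_coverage, dtype=float) * factor
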