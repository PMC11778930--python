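"""Gene-architecture logic.

A transcript is modelled as three contiguous segments in transcript
coordinates — 5'-UTR, CDS, 3'-UTR — plus the genomic extent of its 3'-UTR.
This module selects the set of 3'-UTRs the colocalization statistic runs
over (expressed, longer than a minimum, and genomically non-overlapping)
and classifies crosslink positions into transcript regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formats_io import GenomeInterval


@dataclass
class TranscriptAnnotation:
    """Single-isoform transcript: segment lengths + genomic 3'-UTR extent.

    Invariants: cds_len >= 3 and divisible by 3; utr3_interval, when
    present, has length utr3_len; sequence, when present, has length
    utr5_len + cds_len + utr3_len.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    utr5_len: int
    cds_len: int
    utr3_len: int
    utr3_interval: GenomeInterval | None = None
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.utr5_len < 0 or self.utr3_len < 0:
            raise ValueError("negative UTR length")
        if self.cds_len < 3 or self.cds_len % 3 != 0:
            raise ValueError(f"cds_len {self.cds_len} not a positive multiple of 3")
        if self.utr3_len > 0 and self.utr3_interval is not None:
            if self.utr3_interval.length != self.utr3_len:
                raise ValueError(
                    f"utr3_interval length {self.utr3_interval.length} != utr3_len {self.utr3_len}"
                )
        if self.sequence is not None and len(self.sequence) != self.transcript_length:
            raise ValueError("sequence length != transcript length")

    @property
    def transcript_length(self) -> int:
        return self.utr5_len + self.cds_len + self.utr3_len

    @property
    def n_codons(self) -> int:
        return self.cds_len // 3

    @property
    def utr3_sequence(self) -> str | None:
        if self.sequence is None or self.utr3_len == 0:
            return None
        return self.sequence[self.utr5_len + self.cds_len :]


def compute_tpm(counts: Sequence[float], lengths: Sequence[float]) -> np.ndarray:
    """Transcripts per million: 1e6 * (c_i/L_i) / sum_j (c_j/L_j).

    All-zero counts leave the normalization undefined and raise.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("transcript lengths must be positive")
    if np.any(counts < 0):
        raise ValueError("negative counts")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        raise ValueError("all counts are zero; TPM undefined")
    return 1e6 * rate / total


def select_analysis_utr3s(
    annotations: Iterable[TranscriptAnnotation],
    tpm: Mapping[str, float],
    tpm_min: float = 1.0,
    min_len: int = 50,
    same_strand: bool = False,
) -> list[TranscriptAnnotation]:
    """Select the non-overlapping expressed 3'-UTRs used by the association.

    Keeps transcripts with TPM strictly greater than ``tpm_min`` and 3'-UTR
    strictly longer than ``min_len`` nt, then removes *every* member of any
    genomically overlapping cluster (>=1 shared base, strand ignored by
    default).  Discarding whole clusters — rather than keeping one isoform —
    removes isoform ambiguity symmetrically.
    """
    candidates = [
        a
        for a in annotations
        if a.utr3_interval is not None
        and a.utr3_len > min_len
        and tpm[a.transcript_id] > tpm_min
    ]
    # sweep per chromosome (or chrom+strand): mark anything touching a neighbor
    keyfn = (lambda a: (a.chrom, a.strand)) if same_strand else (lambda a: a.chrom)
    by_key: dict = {}
    for a in candidates:
        by_key.setdefault(keyfn(a), []).append(a)
    overlapping: set[str] = set()
    for group in by_key.values():
        group.sort(key=lambda a: (a.utr3_interval.start, a.utr3_interval.end))
        run_end = -1  # rightmost end seen in the current overlap run
        run_members: list[TranscriptAnnotation] = []
        for a in group:
            iv = a.utr3_interval
            if iv.start < run_end:
                run_members.append(a)
                run_end = max(run_end, iv.end)
            else:
                if len(run_members) > 1:
                    overlapping.update(m.transcript_id for m in run_members)
                run_members = [a]
                run_end = iv.end
        if len(run_members) > 1:
            overlapping.update(m.transcript_id for m in run_members)
    kept = [a for a in candidates if a.transcript_id not in overlapping]
    return kept


def classify_positions(
    positions: Iterable[tuple[str, int]],
    annotations: Mapping[str, TranscriptAnnotation] | Iterable[TranscriptAnnotation],
) -> dict:
    """Classify transcript-coordinate points into 5'-UTR / CDS / 3'-UTR.

    ``positions`` is an iterable of (transcript_id, position).  Boundaries
    are half-open: position utr5_len is the first CDS base.  Positions
    outside transcript bounds (or on unknown transcripts) are tallied under
    "unassigned" and excluded from the fractions, which otherwise sum to 1.
    """
    if not isinstance(annotations, Mapping):
        annotations = {a.transcript_id: a for a in annotations}
    counts = {"utr5": 0, "cds": 0, "utr3": 0, "unassigned": 0}
    for tid, pos in positions:
        ann = annotations.get(tid)
        if ann is None or pos < 0 or pos >= ann.transcript_length:
            counts["unassigned"] += 1
        elif pos < ann.utr5_len:
            counts["utr5"] += 1
        elif pos < ann.utr5_len + ann.cds_len:
            counts["cds"] += 1
        else:
            counts["utr3"] += 1
    assigned = counts["utr5"] + counts["cds"] + counts["utr3"]
    fractions = {
        k: (counts[k] / assigned if assigned else float("nan"))
        for k in ("utr5", "cds", "utr3")
    }
    return {"counts": counts, "fractions": fractions, "n_assigned": assigned}
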