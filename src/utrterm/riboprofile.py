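"""P1-nuclease ribosome-profiling computation.

Footprint classes: monosome libraries yield 32-40 nt monosome footprints;
disome libraries split at 60 nt into sub-disome (<60) and true disome
(>=60).  A-site codons are assigned from the reading frame of the read's
5' end via a frame-indexed offset map; the default {0: 15, 1: 16, 2: 17}
maps all three frames of one footprint population onto the same codon and
is overridable.  CDS occupancy counts a read iff its A-site codon lies in
the inclusive 1-based window [15, n_codons - 10].  Metagene profiles are
length-stratified, per-gene rescaled by mean reads per codon, and averaged
over the genes passing the structure filters (>=50 nt 5'-UTR, >=450 nt
CDS, >=50 nt 3'-UTR, >=1 mean reads per codon).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .transcript_model import TranscriptAnnotation

DEFAULT_OFFSETS: dict[int, int] = {0: 15, 1: 16, 2: 17}

MONOSOME_MIN, MONOSOME_MAX = 32, 40
TRUE_DISOME_MIN = 60


@dataclass
class FootprintAlignment:
    """One footprint in transcript coordinates (0-based 5' end)."""

    transcript_id: str
    five_prime_pos: int
    length: int
    sample: str = ""
    footprint_class: str = "unassigned"

    def __post_init__(self) -> None:
        if self.five_prime_pos < 0:
            raise ValueError("negative five_prime_pos")
        if self.length < 1:
            raise ValueError("length must be >= 1")


def classify_footprint(length: int, library: str) -> str:
    """Assign the footprint class from read length and library type."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if library == "monosome_lib":
        return "monosome" if MONOSOME_MIN <= length <= MONOSOME_MAX else "unassigned"
    if library == "disome_lib":
        return "true_disome" if length >= TRUE_DISOME_MIN else "sub_disome"
    raise ValueError(f"unknown library {library!r}")


def validate_offsets(offsets: Mapping[int, int]) -> dict[int, int]:
    if set(offsets) != {0, 1, 2}:
        raise ValueError("offset map must cover frames 0, 1, 2")
    if any(v < 0 for v in offsets.values()):
        raise ValueError("offsets must be >= 0")
    return {int(k): int(v) for k, v in offsets.items()}


def assign_a_site(
    fp: FootprintAlignment,
    annotation: TranscriptAnnotation,
    offsets: Mapping[int, int] = DEFAULT_OFFSETS,
) -> int:
    """A-site codon index (0-based from the start codon) for one footprint.

    frame = (five_prime_pos - utr5_len) mod 3; the A-site first base is
    five_prime_pos + offsets[frame]; the codon index may be negative
    (5'-UTR) or >= n_codons (3'-UTR) and is returned as-is.
    """
    if annotation is None:
        raise ValueError("annotation required for A-site assignment")
    offsets = validate_offsets(offsets)
    frame = (fp.five_prime_pos - annotation.utr5_len) % 3
    a_site_nt = fp.five_prime_pos + offsets[frame]
    return (a_site_nt - annotation.utr5_len) // 3


def assign_a_sites(
    five_prime_pos: np.ndarray,
    utr5_len: np.ndarray,
    offsets: Mapping[int, int] = DEFAULT_OFFSETS,
) -> np.ndarray:
    """Vectorized A-site codon assignment (floor division, mathematical mod)."""
    offsets = validate_offsets(offsets)
    five_prime_pos = np.asarray(five_prime_pos, dtype=np.int64)
    utr5_len = np.asarray(utr5_len, dtype=np.int64)
    frame = (five_prime_pos - utr5_len) % 3
    off = np.asarray([offsets[0], offsets[1], offsets[2]], dtype=np.int64)[frame]
    return np.floor_divide(five_prime_pos + off - utr5_len, 3)


def _annotation_frame(
    annotations: Mapping[str, TranscriptAnnotation] | Iterable[TranscriptAnnotation],
) -> pd.DataFrame:
    if not isinstance(annotations, Mapping):
        annotations = {a.transcript_id: a for a in annotations}
    return pd.DataFrame(
        {
            "transcript_id": list(annotations),
            "gene_id": [a.gene_id for a in annotations.values()],
            "utr5_len": [a.utr5_len for a in annotations.values()],
            "cds_len": [a.cds_len for a in annotations.values()],
            "utr3_len": [a.utr3_len for a in annotations.values()],
        }
    ).set_index("transcript_id")


def footprints_to_frame(footprints) -> pd.DataFrame:
    if isinstance(footprints, pd.DataFrame):
        return footprints
    return pd.DataFrame(
        {
            "transcript_id": [f.transcript_id for f in footprints],
            "five_prime_pos": [f.five_prime_pos for f in footprints],
            "length": [f.length for f in footprints],
            "sample": [f.sample for f in footprints],
        }
    )


def cds_occupancy_counts(
    footprints,
    annotations,
    offsets: Mapping[int, int] = DEFAULT_OFFSETS,
    first_codon: int = 15,
    last_codon_from_end: int = 10,
) -> pd.DataFrame:
    """Per-gene read counts restricted to the CDS occupancy window.

    A read counts for its gene iff its A-site codon c (1-based) satisfies
    first_codon <= c <= n_codons - last_codon_from_end.  Returns a
    gene-by-sample count matrix.
    """
    df = footprints_to_frame(footprints)
    ann = _annotation_frame(annotations)
    merged = df.join(ann, on="transcript_id", how="inner")
    codon0 = assign_a_sites(
        merged["five_prime_pos"].to_numpy(), merged["utr5_len"].to_numpy(), offsets
    )
    codon1 = codon0 + 1
    n_codons = merged["cds_len"].to_numpy() // 3
    in_window = (codon1 >= first_codon) & (codon1 <= n_codons - last_codon_from_end)
    kept = merged.loc[in_window]
    counts = (
        kept.groupby(["gene_id", "sample"], sort=True).size().unstack(fill_value=0)
    )
    # genes with zero in-window reads still belong to the matrix
    all_genes = sorted(ann["gene_id"].unique())
    all_samples = sorted(df["sample"].unique())
    counts = counts.reindex(index=all_genes, columns=all_samples, fill_value=0)
    counts.index.name = "gene_id"
    counts.columns.name = "sample"
    return counts.astype(int)


@dataclass
class MetageneProfile:
    """Length-stratified mean rescaled occupancy around an anchor base.

    ``matrix[i, j]`` is the mean (over genes) rescaled count for length bin
    ``lengths[i]`` at relative position ``positions[j]``; position 0 is the
    first nucleotide of the anchor codon and positions refer to read 5'
    ends.
    """

    anchor: str
    positions: np.ndarray
    lengths: list
    matrix: np.ndarray
    n_genes: int

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.matrix.shape != (len(self.lengths), len(self.positions)):
            raise ValueError("matrix shape does not match lengths x positions")

    def position_sums(self) -> np.ndarray:
        """Profile summed over length bins (one value per relative position)."""
        return self.matrix.sum(axis=0)


def metagene_profile(
    footprints,
    annotations,
    anchor: str = "start_codon",
    min_utr5: int = 50,
    min_cds: int = 450,
    min_utr3: int = 50,
    min_reads_per_codon: float = 1.0,
    position_range: tuple[int, int] = (-50, 150),
    offsets: Mapping[int, int] = DEFAULT_OFFSETS,
) -> MetageneProfile:
    """Length-stratified rescaled metagene profile around start or stop codon.

    Per passing gene g, scale_g = (# reads with A-site in the CDS) /
    n_codons(g); every read of g whose 5' end lies at relative position r
    within ``position_range`` contributes 1/scale_g to cell (length, r);
    cells are summed over genes and divided by the number of passing genes,
    so the profile is depth-invariant per gene.
    """
    if anchor not in ("start_codon", "stop_codon"):
        raise ValueError(f"unknown anchor {anchor!r}")
    if not isinstance(annotations, Mapping):
        annotations = {a.transcript_id: a for a in annotations}
    df = footprints_to_frame(footprints)
    ann = _annotation_frame(annotations)

    structure_ok = ann[
        (ann["utr5_len"] >= min_utr5)
        & (ann["cds_len"] >= min_cds)
        & (ann["utr3_len"] >= min_utr3)
    ]
    attrition = {
        "n_transcripts": len(ann),
        "pass_structure": len(structure_ok),
    }
    merged = df.join(ann, on="transcript_id", how="inner")
    merged = merged[merged["transcript_id"].isin(structure_ok.index)]

    codon0 = assign_a_sites(
        merged["five_prime_pos"].to_numpy(), merged["utr5_len"].to_numpy(), offsets
    )
    n_codons = merged["cds_len"].to_numpy() // 3
    in_cds = (codon0 >= 0) & (codon0 < n_codons)
    cds_reads = (
        pd.Series(in_cds.astype(int), index=merged.index)
        .groupby(merged["transcript_id"])
        .sum()
    )
    scale = cds_reads / (structure_ok.loc[cds_reads.index, "cds_len"] // 3)
    passing = scale[scale >= min_reads_per_codon]
    attrition["pass_reads_per_codon"] = len(passing)
    if len(passing) == 0:
        raise ValueError(f"no genes pass metagene filters: {attrition}")

    merged = merged[merged["transcript_id"].isin(passing.index)]
    lo, hi = position_range
    anchor_nt = merged["utr5_len"].to_numpy().copy()
    if anchor == "stop_codon":
        anchor_nt = anchor_nt + merged["cds_len"].to_numpy() - 3
    rel = merged["five_prime_pos"].to_numpy() - anchor_nt
    in_range = (rel >= lo) & (rel <= hi)
    merged = merged.loc[in_range]
    rel = rel[in_range]

    lengths = sorted(merged["length"].unique().tolist())
    positions = np.arange(lo, hi + 1)
    matrix = np.zeros((len(lengths), positions.size))
    if len(merged):
        li = pd.Series(range(len(lengths)), index=lengths)
        rows = li[merged["length"].to_numpy()].to_numpy()
        cols = rel - lo
        weights = (1.0 / passing[merged["transcript_id"].to_numpy()]).to_numpy()
        np.add.at(matrix, (rows, cols), weights)
    matrix /= len(passing)
    return MetageneProfile(
        anchor=anchor,
        positions=positions,
        lengths=[int(l) for l in lengths],
        matrix=matrix,
        n_genes=len(passing),
    )


def bin_profile_lengths(
    profile: MetageneProfile, bins: Sequence[tuple[int, int]]
) -> MetageneProfile:
    """Sum profile rows within inclusive, non-overlapping length ranges."""
    sorted_bins = sorted(bins)
    for lo, hi in sorted_bins:
        if hi < lo:
            raise ValueError(f"invalid length bin ({lo}, {hi})")
    for (_, hi1), (lo2, _) in zip(sorted_bins, sorted_bins[1:]):
        if lo2 <= hi1:
            raise ValueError("length bins must be non-overlapping")
    matrix = np.zeros((len(bins), profile.positions.size))
    for i, (lo, hi) in enumerate(bins):
        rows = [j for j, L in enumerate(profile.lengths) if lo <= L <= hi]
        if rows:
            matrix[i] = profile.matrix[rows].sum(axis=0)
    return MetageneProfile(
        anchor=profile.anchor,
        positions=profile.positions.copy(),
        lengths=[tuple(b) for b in bins],
        matrix=matrix,
        n_genes=profile.n_genes,
    )


def profile_to_frame(profile: MetageneProfile) -> pd.DataFrame:
    """Profile as a TSV-ready frame: rows = relative position, cols = bins."""
    cols = {
        (f"{L[0]}-{L[1]}" if isinstance(L, tuple) else str(L)): profile.matrix[i]
        for i, L in enumerate(profile.lengths)
    }
    return pd.DataFrame(cols, index=pd.Index(profile.positions, name="position"))
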