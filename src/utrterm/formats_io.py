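"""Readers and writers for the plain-text formats the pipeline exchanges.

Coordinate convention: every interval in memory is 0-based half-open,
matching BED, so BED I/O is the identity on coordinates.  Transcript
annotations are consumed from a simplified TSV (one single-isoform
transcript per row, segment lengths plus the genomic extent of the 3'-UTR)
rather than full GTF exon chains; ribosome footprint alignments are in
transcript coordinates, as produced by transcriptome alignment.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """A malformed external file; the message names the offending line/row."""


@dataclass(frozen=True)
class GenomeInterval:
    """A 0-based half-open genomic interval with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        """>=1 shared base, strand ignored."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class Peak:
    """An assay interval from one biological replicate."""

    interval: GenomeInterval
    score: float = 0.0
    replicate: str = ""
    name: str = "."


TRANSCRIPT_TABLE_COLUMNS = (
    "transcript_id",
    "gene_id",
    "chrom",
    "strand",
    "utr5_len",
    "cds_len",
    "utr3_len",
    "utr3_start",
    "utr3_end",
)


def read_bed_peaks(path, replicate_label: str = "") -> list[Peak]:
    """Read a BED(3+) file into peaks.

    Column 5 (score) defaults to 0 when absent; column 6 (strand) defaults
    to '+'.  Malformed lines (non-integer coordinates, start >= end) reject
    the whole file with the 1-based line number.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] else "."
            score = 0.0
            if len(fields) > 4 and fields[4] not in ("", "."):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: line {lineno}: non-numeric score"
                    ) from exc
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "+"
            try:
                interval = GenomeInterval(chrom, start, end, strand)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            peaks.append(Peak(interval, score=score, replicate=replicate_label, name=name))
    return peaks


def write_bed_peaks(peaks: Iterable[Peak], path) -> None:
    """Write peaks as BED6; exact round-trip of coordinates and scores."""
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t{p.score!r}\t{iv.strand}\n"
            )


def write_bed_intervals(intervals: Iterable[GenomeInterval], path) -> None:
    """Write bare intervals as BED3 (used for reproducible peak sets)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_transcript_table(path) -> list:
    """Read the simplified transcript annotation TSV.

    Required header columns: transcript_id, gene_id, chrom, strand,
    utr5_len, cds_len, utr3_len, utr3_start, utr3_end.  ``utr3_start`` and
    ``utr3_end`` give the genomic extent of the 3'-UTR (0-based half-open);
    both are -1 (or empty) when utr3_len == 0.  Rows with a CDS length not
    divisible by 3 and files with duplicate transcript_ids are rejected.
    An optional ``sequence`` column carries the transcript sequence.
    """
    from .transcript_model import TranscriptAnnotation

    annotations: list[TranscriptAnnotation] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(
            (ln for ln in fh if not ln.startswith("#")), delimiter="\t"
        )
        missing = set(TRANSCRIPT_TABLE_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        for rowno, row in enumerate(reader, start=2):
            tid = row["transcript_id"]
            if tid in seen:
                raise FormatError(f"{path}: duplicate transcript_id {tid!r}")
            seen.add(tid)
            try:
                utr5 = int(row["utr5_len"])
                cds = int(row["cds_len"])
                utr3 = int(row["utr3_len"])
            except ValueError as exc:
                raise FormatError(f"{path}: row {rowno}: non-integer length") from exc
            if cds % 3 != 0:
                raise FormatError(
                    f"{path}: row {rowno} ({tid}): cds_len {cds} not a multiple of 3"
                )
            utr3_interval = None
            if utr3 > 0:
                try:
                    u3s, u3e = int(row["utr3_start"]), int(row["utr3_end"])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: row {rowno}: non-integer 3'-UTR extent"
                    ) from exc
                utr3_interval = GenomeInterval(row["chrom"], u3s, u3e, row["strand"])
            seq = row.get("sequence") or None
            try:
                annotations.append(
                    TranscriptAnnotation(
                        transcript_id=tid,
                        gene_id=row["gene_id"],
                        chrom=row["chrom"],
                        strand=row["strand"],
                        utr5_len=utr5,
                        cds_len=cds,
                        utr3_len=utr3,
                        utr3_interval=utr3_interval,
                        sequence=seq,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}: row {rowno} ({tid}): {exc}") from exc
    return annotations


def write_transcript_table(annotations: Iterable, path, with_sequence: bool = False) -> None:
    cols = list(TRANSCRIPT_TABLE_COLUMNS) + (["sequence"] if with_sequence else [])
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for ann in annotations:
            u3 = ann.utr3_interval
            row = [
                ann.transcript_id,
                ann.gene_id,
                ann.chrom,
                ann.strand,
                str(ann.utr5_len),
                str(ann.cds_len),
                str(ann.utr3_len),
                str(u3.start if u3 else -1),
                str(u3.end if u3 else -1),
            ]
            if with_sequence:
                row.append(ann.sequence or "")
            fh.write("\t".join(row) + "\n")


FOOTPRINT_TABLE_COLUMNS = ("transcript_id", "five_prime_pos", "length", "sample")


def read_footprint_table(path) -> list:
    """Read a transcript-coordinate footprint alignment TSV.

    Positions are 0-based 5' ends.  A negative position or a length < 1
    rejects the row (with its number); consistency with transcript length
    is checked downstream when an annotation is attached.
    """
    from .riboprofile import FootprintAlignment

    df = read_footprint_frame(path)
    return [
        FootprintAlignment(r.transcript_id, int(r.five_prime_pos), int(r.length), r.sample)
        for r in df.itertuples(index=False)
    ]


def read_footprint_frame(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(FOOTPRINT_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    bad = df.index[(df["five_prime_pos"] < 0) | (df["length"] < 1)]
    if len(bad):
        raise FormatError(
            f"{path}: row {bad[0] + 2}: negative five_prime_pos or length < 1"
        )
    return df


def write_footprint_table(footprints: pd.DataFrame, path) -> None:
    footprints.to_csv(path, sep="\t", index=False, columns=list(FOOTPRINT_TABLE_COLUMNS))


def read_fasta(path) -> dict[str, str]:
    """FASTA as {id: sequence}; headers are transcript_ids."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_count_matrix(path) -> pd.DataFrame:
    """Gene-by-sample counts TSV; first column is the gene id."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate gene or sample identifiers")
    return df


def write_count_matrix(counts: pd.DataFrame, path, index_label: str = "gene_id") -> None:
    counts.to_csv(path, sep="\t", index_label=index_label)


def write_bedgraph(coverage: Mapping[str, np.ndarray], path) -> None:
    """Write per-base coverage as 4-column bedGraph.

    Adjacent equal-valued runs are merged and zero-valued runs are omitted
    (the sparse convention).  Arrays start at genomic position 0.  Values
    are written with 8 significant digits.
    """
    with open(path, "w") as fh:
        for chrom in coverage:
            values = np.asarray(coverage[chrom], dtype=float)
            if np.any(values < 0):
                raise ValueError(f"negative coverage on {chrom}")
            if values.size == 0:
                continue
            # run boundaries where the value changes
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [values.size]))
            for s, e in zip(starts, ends):
                v = values[s]
                if v == 0:
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.8g}\n")
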