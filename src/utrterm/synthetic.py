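"""Synthetic-data generator with planted, recorded ground truth.

Every input the pipeline consumes can be produced here: a single-isoform
transcriptome whose polyadenylated 3'-UTRs carry a canonical PAS hexamer
near the terminus, replicated APA and CLIP peak sets with a planted
colocalization odds ratio, P1-style monosome/disome footprints whose 5'
ends invert the A-site offset map exactly, and negative-binomial count
matrices with planted per-gene abundance and translation efficiency.

Every output is a pure function of (seed, config); the planted parameters
are recorded in a ``SyntheticTruth`` object serialized alongside the data
so each pipeline stage can be closed-loop tested.

Association is simulated at the UTR presence/absence level, matching the
contingency construction downstream: APA presence marks polyadenylated
UTRs with a detectable APA peak, and CLIP presence is Bernoulli with
log-odds shifted by log(target odds ratio) on APA-positive UTRs while the
marginal CLIP rate is held at a configured base rate.  Replicates then
realize each present peak with positional jitter and independent dropout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .formats_io import GenomeInterval, Peak
from .peaklib import ReplicatePeakSet
from .riboprofile import DEFAULT_OFFSETS, validate_offsets
from .transcript_model import TranscriptAnnotation

_BASES = np.array(list("ACGT"))
PAS_DNA = "AATAAA"


@dataclass
class SyntheticTruth:
    """Planted ground truth for one generated dataset."""

    seed: int
    config: dict
    transcripts: pd.DataFrame
    extras: dict[str, Any] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "config": self.config,
            "transcripts": {
                "index": self.transcripts.index.tolist(),
                "columns": {
                    c: np.asarray(self.transcripts[c]).tolist()
                    for c in self.transcripts.columns
                },
            },
            "extras": {
                k: (np.asarray(v).tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.extras.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        tx = pd.DataFrame(
            payload["transcripts"]["columns"],
            index=pd.Index(payload["transcripts"]["index"], name="transcript_id"),
        )
        return cls(payload["seed"], payload["config"], tx, payload["extras"])


def generate_transcriptome(
    n_genes: int = 2000,
    seed: int = 0,
    frac_polyadenylated: float = 0.85,
    frac_long_cds: float = 0.85,
    pas_terminal_window: tuple[int, int] = (10, 40),
    mean_utr5: int = 120,
    mean_utr3: int = 300,
    min_utr3: int = 60,
    max_utr3: int = 2000,
    intergenic_gap: int = 200,
    chrom: str = "chr1",
) -> tuple[list[TranscriptAnnotation], SyntheticTruth]:
    """Random-composition transcriptome with planted terminal PAS hexamers.

    Polyadenylated transcripts (fraction ``frac_polyadenylated``) get one
    AAUAAA planted with its start uniformly 10-40 nt upstream of the motif
    end's distance to the 3' terminus, i.e. start in
    [L - w_hi - 6, L - w_lo - 6]; non-polyadenylated (histone-like)
    transcripts get none planted and are flagged.  A fraction
    ``frac_long_cds`` of CDSs is >= 450 nt so metagene filters can pass.
    3'-UTRs are placed non-overlapping along one chromosome with
    alternating random strand.
    """
    if not (0 <= frac_polyadenylated <= 1):
        raise ValueError("frac_polyadenylated must be in [0, 1]")
    rng = np.random.default_rng(seed)
    w_lo, w_hi = pas_terminal_window
    min_feasible_utr3 = w_hi + 6 + 1
    if min_utr3 < min_feasible_utr3:
        min_utr3 = min_feasible_utr3

    utr5 = np.clip(
        np.round(rng.lognormal(np.log(mean_utr5), 0.5, n_genes)).astype(int), 20, 600
    )
    long_cds = rng.random(n_genes) < frac_long_cds
    codons = np.where(
        long_cds, rng.integers(150, 900, n_genes), rng.integers(34, 150, n_genes)
    )
    cds = codons * 3
    utr3 = np.clip(
        np.round(rng.lognormal(np.log(mean_utr3), 0.6, n_genes)).astype(int),
        min_utr3,
        max_utr3,
    )
    poly = rng.random(n_genes) < frac_polyadenylated
    # PAS start: motif occupies [s, s+6); its start is placed so the motif
    # lies 10-40 nt upstream of the 3' terminus
    pas_local = np.where(
        poly, utr3 - 6 - rng.integers(w_lo, w_hi + 1, n_genes), -1
    )
    strand = np.where(rng.random(n_genes) < 0.5, "+", "-")

    annotations: list[TranscriptAnnotation] = []
    cursor = 1000
    for i in range(n_genes):
        total = utr5[i] + cds[i] + utr3[i]
        seq = "".join(_BASES[rng.integers(0, 4, total)])
        if poly[i]:
            p = utr5[i] + cds[i] + pas_local[i]
            seq = seq[:p] + PAS_DNA + seq[p + 6 :]
        iv = GenomeInterval(chrom, cursor, cursor + int(utr3[i]), str(strand[i]))
        cursor += int(utr3[i]) + intergenic_gap
        annotations.append(
            TranscriptAnnotation(
                transcript_id=f"t{i:05d}",
                gene_id=f"g{i:05d}",
                chrom=chrom,
                strand=str(strand[i]),
                utr5_len=int(utr5[i]),
                cds_len=int(cds[i]),
                utr3_len=int(utr3[i]),
                utr3_interval=iv,
                sequence=seq,
            )
        )
    truth = SyntheticTruth(
        seed=seed,
        config={
            "n_genes": n_genes,
            "frac_polyadenylated": frac_polyadenylated,
            "frac_long_cds": frac_long_cds,
            "pas_terminal_window": list(pas_terminal_window),
        },
        transcripts=pd.DataFrame(
            {
                "gene_id": [a.gene_id for a in annotations],
                "strand": strand,
                "utr5_len": utr5,
                "cds_len": cds,
                "utr3_len": utr3,
                "polyadenylated": poly,
                "pas_local": pas_local,
            },
            index=pd.Index([a.transcript_id for a in annotations], name="transcript_id"),
        ),
    )
    return annotations, truth


def solve_conditional_rates(
    marginal: float, p_apa: float, odds_ratio: float
) -> tuple[float, float]:
    """CLIP rates (p0 for APA-negative, p1 for APA-positive) with a fixed
    marginal rate and a fixed odds ratio p1/(1-p1) : p0/(1-p0)."""
    if odds_ratio <= 0:
        raise ValueError("target_odds_ratio must be > 0")
    if not (0 < marginal < 1):
        raise ValueError("marginal CLIP rate must be in (0, 1)")
    if odds_ratio == 1 or p_apa in (0.0, 1.0):
        return marginal, marginal

    def p1_of(p0: float) -> float:
        return odds_ratio * p0 / (1 + (odds_ratio - 1) * p0)

    f = lambda p0: p_apa * p1_of(p0) + (1 - p_apa) * p0 - marginal
    p0 = brentq(f, 1e-12, 1 - 1e-12, xtol=1e-14)
    return float(p0), float(p1_of(p0))


def _local_to_genomic(utr: GenomeInterval, s: int, e: int) -> GenomeInterval:
    """UTR-local (5'->3') [s, e) to genomic coordinates, strand-aware."""
    if utr.strand == "+":
        return GenomeInterval(utr.chrom, utr.start + s, utr.start + e, "+")
    return GenomeInterval(utr.chrom, utr.end - e, utr.end - s, "-")


def simulate_peaks(
    annotations: Sequence[TranscriptAnnotation],
    truth: SyntheticTruth,
    assay: str,
    n_replicates: int = 3,
    seed: int = 0,
    target_odds_ratio: float = 1.0,
    clip_base_rate: float = 0.05,
    apa_rate: float = 1.0,
    peak_width: tuple[int, int] = (20, 40),
    jitter_sd: float = 2.0,
    dropout_rate: float = 0.0,
) -> ReplicatePeakSet:
    """Replicated peak sets with planted presence/absence association.

    APA: peaks are placed at the PAS of polyadenylated UTRs, each detected
    with probability ``apa_rate`` (APA-seq depth is finite, so not every
    polyadenylated transcript yields a reproducible peak).  CLIP: presence
    is Bernoulli with log-odds shifted by log(target_odds_ratio) on
    APA-present UTRs, holding the marginal rate at ``clip_base_rate``;
    requires APA to have been simulated first on the same truth.  Each
    replicate realizes present peaks with rounded-normal positional jitter
    and independent dropout.  Presence indicators are recorded in
    ``truth.extras``.
    """
    if not 0 <= dropout_rate < 1:
        raise ValueError(f"dropout_rate must be in [0, 1), got {dropout_rate}")
    rng = np.random.default_rng(seed)
    n = len(annotations)
    tx = truth.transcripts
    utr3_len = tx["utr3_len"].to_numpy()
    pas_local = tx["pas_local"].to_numpy()

    width = rng.integers(peak_width[0], peak_width[1] + 1, n)
    width = np.minimum(width, utr3_len)

    if assay == "APA":
        present = tx["polyadenylated"].to_numpy() & (rng.random(n) < apa_rate)
        center = np.where(pas_local >= 0, pas_local + 3, utr3_len // 2)
    elif assay == "CLIP":
        if "apa_present" not in truth.extras:
            raise ValueError("simulate APA peaks before CLIP on the same truth")
        apa_present = np.asarray(truth.extras["apa_present"], dtype=bool)
        p_apa = float(apa_present.mean())
        p0, p1 = solve_conditional_rates(clip_base_rate, p_apa, target_odds_ratio)
        present = rng.random(n) < np.where(apa_present, p1, p0)
        center = np.where(pas_local >= 0, pas_local + 3, utr3_len // 2)
    else:
        raise ValueError(f"unknown assay {assay!r}")

    start0 = np.clip(center - width // 2, 0, utr3_len - width)
    replicates: list[list[Peak]] = []
    for r in range(n_replicates):
        jitter = np.round(rng.normal(0.0, jitter_sd, n)).astype(int)
        starts = np.clip(start0 + jitter, 0, utr3_len - width)
        kept = present & (rng.random(n) >= dropout_rate)
        label = f"{assay}_rep{r + 1}"
        peaks = [
            Peak(
                _local_to_genomic(
                    annotations[i].utr3_interval, int(starts[i]), int(starts[i] + width[i])
                ),
                score=1.0,
                replicate=label,
                name=annotations[i].transcript_id,
            )
            for i in np.flatnonzero(kept)
        ]
        replicates.append(peaks)
    truth.extras[f"{assay.lower()}_present"] = present.astype(bool)
    truth.config[f"{assay.lower()}_peaks"] = {
        "n_replicates": n_replicates,
        "target_odds_ratio": target_odds_ratio if assay == "CLIP" else None,
        "clip_base_rate": clip_base_rate if assay == "CLIP" else None,
        "apa_rate": apa_rate if assay == "APA" else None,
        "jitter_sd": jitter_sd,
        "dropout_rate": dropout_rate,
        "seed": seed,
    }
    return ReplicatePeakSet(
        assay=assay,
        replicates=replicates,
        labels=[f"{assay}_rep{r + 1}" for r in range(n_replicates)],
    )


def simulate_pas_study_peaks(
    annotations: Sequence[TranscriptAnnotation],
    truth: SyntheticTruth,
    n_peaks: int = 1000,
    pas_fraction: float = 0.58,
    flank: int = 25,
    peak_width: int = 20,
    seed: int = 0,
    mode: str = "planted_fraction",
) -> tuple[list[tuple[GenomeInterval, TranscriptAnnotation]], np.ndarray]:
    """Crosslink-style peaks with a planted PAS-in-window fraction.

    ``planted_fraction``: round(n_peaks * pas_fraction) peaks are placed so
    the flanked window contains the UTR's PAS; the rest are placed (by
    rejection) in PAS-free windows.  ``on_pas``: every peak starts exactly
    on the PAS (maximal enrichment).  Returns (peak, annotation) pairs plus
    the planted flags.
    """
    from .pas_motif import find_pas

    rng = np.random.default_rng(seed)
    tx = truth.transcripts
    with_pas = [
        i
        for i, a in enumerate(annotations)
        if tx["pas_local"].iloc[i] >= 0 and a.utr3_len >= peak_width
    ]
    if not with_pas:
        raise ValueError("no PAS-bearing UTRs available")
    assigned: list[tuple[GenomeInterval, TranscriptAnnotation]] = []
    planted_flags: list[bool] = []

    def add_peak(i: int, s: int) -> None:
        ann = annotations[i]
        iv = _local_to_genomic(ann.utr3_interval, s, s + peak_width)
        assigned.append((iv, ann))

    if mode == "on_pas":
        for _ in range(n_peaks):
            i = int(rng.choice(with_pas))
            L = annotations[i].utr3_len
            p = int(tx["pas_local"].iloc[i])
            add_peak(i, int(np.clip(p, 0, L - peak_width)))
            planted_flags.append(True)
        return assigned, np.asarray(planted_flags)
    if mode != "planted_fraction":
        raise ValueError(f"unknown mode {mode!r}")

    n_planted = int(round(n_peaks * pas_fraction))
    hit_cache: dict[int, np.ndarray] = {}

    def hits_of(i: int) -> np.ndarray:
        if i not in hit_cache:
            hit_cache[i] = np.asarray(
                find_pas(annotations[i].utr3_sequence), dtype=np.int64
            )
        return hit_cache[i]

    for _ in range(n_planted):
        for _attempt in range(200):
            i = int(rng.choice(with_pas))
            L = annotations[i].utr3_len
            p = int(tx["pas_local"].iloc[i])
            lo = max(0, p - peak_width - flank + 1)
            hi = min(L - peak_width, p + flank)
            if lo <= hi:
                add_peak(i, int(rng.integers(lo, hi + 1)))
                planted_flags.append(True)
                break
        else:
            raise ValueError("could not place a PAS-covering peak")
    eligible = [i for i, a in enumerate(annotations) if a.utr3_len >= peak_width]
    for _ in range(n_peaks - n_planted):
        for _attempt in range(500):
            i = int(rng.choice(eligible))
            L = annotations[i].utr3_len
            s = int(rng.integers(0, L - peak_width + 1))
            h = hits_of(i)
            w_lo, w_hi = max(0, s - flank), min(L, s + peak_width + flank)
            if np.searchsorted(h, w_hi) == np.searchsorted(h, w_lo):
                add_peak(i, s)
                planted_flags.append(False)
                break
        else:
            raise ValueError("could not place a PAS-free peak")
    truth.extras["pas_peak_planted_fraction"] = n_planted / n_peaks
    return assigned, np.asarray(planted_flags)


def simulate_expression(
    n_genes: int,
    seed: int = 0,
    abundance_sigma: float = 1.0,
    te_sigma: float = 0.8,
) -> tuple[np.ndarray, np.ndarray]:
    """Planted per-gene mRNA abundance and translation efficiency
    (independent log-normals, median 1)."""
    rng = np.random.default_rng(seed)
    abundance = rng.lognormal(0.0, abundance_sigma, n_genes)
    te = rng.lognormal(0.0, te_sigma, n_genes)
    return abundance, te


def _nb_counts(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson; dispersion 0 degenerates to
    Poisson.  Var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    return rng.poisson(rng.gamma(shape, mean * dispersion))


def simulate_count_matrix(
    weights: np.ndarray,
    gene_ids: Sequence[str],
    sample_names: Sequence[str],
    total_reads: float,
    dispersion: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-by-sample NB counts with per-gene mean proportional to weights."""
    rng = np.random.default_rng(seed)
    weights = np.asarray(weights, dtype=float)
    mean = total_reads * weights / weights.sum()
    data = {s: _nb_counts(rng, mean, dispersion) for s in sample_names}
    out = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))
    return out


_MONOSOME_LENGTHS = np.arange(32, 41)
_MONOSOME_PROBS = np.array([1, 2, 3, 4, 5, 4, 3, 2, 1], dtype=float) / 25.0


def _disome_length_dist() -> tuple[np.ndarray, np.ndarray]:
    """Mixture: 40% sub-disome 45-59 nt, 60% true disome 60-75 nt (uniform
    within class); generator defaults, not measured claims."""
    sub = np.arange(45, 60)
    true = np.arange(60, 76)
    lengths = np.concatenate((sub, true))
    probs = np.concatenate(
        (np.full(sub.size, 0.4 / sub.size), np.full(true.size, 0.6 / true.size))
    )
    return lengths, probs


def simulate_footprints(
    annotations: Sequence[TranscriptAnnotation],
    abundance: np.ndarray,
    te: np.ndarray,
    offsets: Mapping[int, int] = DEFAULT_OFFSETS,
    n_reads: int = 200_000,
    seed: int = 0,
    sample: str = "mono_rep1",
    library: str = "monosome_lib",
) -> pd.DataFrame:
    """Ribosome footprints whose 5' ends invert the A-site offsets exactly.

    Per-gene read mass is proportional to abundance x TE; the A-site codon
    is uniform over the CDS; the observed 5'-end frame f is uniform over
    {0, 1, 2} and the 5' end is placed at
    codon_start + ((f + offsets[f]) mod 3) - offsets[f], so frame-based
    A-site assignment with the same offset map recovers the generating
    codon for every in-CDS read.  Lengths follow the monosome (32-40 nt)
    or bimodal disome distribution.
    """
    offsets = validate_offsets(offsets)
    rng = np.random.default_rng(seed)
    n = len(annotations)
    utr5 = np.asarray([a.utr5_len for a in annotations])
    n_codons = np.asarray([a.n_codons for a in annotations])
    mass = np.asarray(abundance, dtype=float) * np.asarray(te, dtype=float)
    gene = rng.choice(n, size=n_reads, p=mass / mass.sum())
    codon = (rng.random(n_reads) * n_codons[gene]).astype(np.int64)
    f = rng.integers(0, 3, n_reads)
    off = np.asarray([offsets[0], offsets[1], offsets[2]])[f]
    f_adj = (f + off) % 3
    five_prime = utr5[gene] + 3 * codon + f_adj - off
    if library == "monosome_lib":
        lengths = rng.choice(_MONOSOME_LENGTHS, size=n_reads, p=_MONOSOME_PROBS)
    elif library == "disome_lib":
        dl, dp = _disome_length_dist()
        lengths = rng.choice(dl, size=n_reads, p=dp)
    else:
        raise ValueError(f"unknown library {library!r}")
    tids = np.asarray([a.transcript_id for a in annotations])
    df = pd.DataFrame(
        {
            "transcript_id": tids[gene],
            "five_prime_pos": five_prime,
            "length": lengths,
            "sample": sample,
            "true_codon": codon,  # generating A-site codon, for closed-loop tests
        }
    )
    if (df["five_prime_pos"] < 0).any():
        # short 5'-UTRs cannot accommodate the offset upstream of codon 0
        df = df[df["five_prime_pos"] >= 0].reset_index(drop=True)
    return df


def simulate_clip_utr3_counts(
    abundance: np.ndarray,
    te: np.ndarray,
    gene_ids: Sequence[str],
    total_reads: float = 1e6,
    coupling: float = 0.8,
    noise_sigma: float = 0.5,
    seed: int = 0,
) -> pd.Series:
    """3'-UTR CLIP read counts coupled to translational output.

    Terminal CLIP signal tracks ribosome output (abundance x TE) with a
    sublinear coupling exponent and multiplicative log-normal noise, so
    the planted correlation with footprint counts is strong and the
    correlation with TE alone is weaker.
    """
    rng = np.random.default_rng(seed)
    mass = (np.asarray(abundance) * np.asarray(te)) ** coupling
    mass = mass * rng.lognormal(0.0, noise_sigma, mass.size)
    mean = total_reads * mass / mass.sum()
    counts = rng.poisson(mean)
    return pd.Series(counts, index=pd.Index(gene_ids, name="gene_id"), name="clip_utr3")
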