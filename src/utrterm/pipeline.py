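"""End-to-end orchestration of the synthetic study.

``run_full`` executes: transcriptome + expression simulation -> replicated
APA/CLIP peak simulation -> analysis-UTR selection (TPM > 1, 3'-UTR >
50 nt, non-overlapping) -> Fisher colocalization -> PAS motif statistics
on CLIP peaks -> ribosome-profiling metagene and occupancy -> TE table ->
CLIP-RPKM correlations, and returns one machine-readable report.  All
randomness derives from a single integer seed.
"""

from __future__ import annotations

import bisect
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import coloc_stats, formats_io, pas_motif, quant, riboprofile, synthetic
from .transcript_model import compute_tpm, select_analysis_utr3s


def demo_config(seed: int = 0) -> dict:
    """The bundled demo: 2,000 genes with a planted odds ratio of 5.6."""
    return {
        "seed": int(seed),
        "n_genes": 2000,
        "frac_polyadenylated": 0.85,
        "apa_rate": 0.12,
        "target_odds_ratio": 5.6,
        "clip_base_rate": 0.05,
        "n_replicates": 3,
        "jitter_sd": 2.0,
        "dropout_rate": 0.05,
        "tpm_min": 1.0,
        "utr3_min_len": 50,
        "flank": 25,
        "n_shuffles": 1000,
        "offsets": dict(riboprofile.DEFAULT_OFFSETS),
        "metagene": {"min_utr5": 50, "min_cds": 450, "min_utr3": 50,
                     "min_reads_per_codon": 1.0},
        "occupancy_window": {"first_codon": 15, "last_codon_from_end": 10},
        "trim_pct": 99.0,
        "n_footprint_reads": 200_000,
        "n_mrna_reads": 200_000,
        "n_rpf_reads": 200_000,
        "n_clip_reads": 1_000_000,
        "mrna_dispersion": 0.05,
        "rpf_dispersion": 0.01,
        "abundance_sigma": 1.0,
        "te_sigma": 0.8,
        "te_shift_sigma": 0.25,
    }


def _stage_seeds(seed: int, n: int = 16) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(x % (2**31)) for x in state]


def run_full(config: dict | None = None, outdir: str | Path | None = None) -> dict:
    """Run the whole synthetic study; optionally write all artifacts.

    Returns the report dict (association, PAS enrichment, metagene
    summary, TE summary, correlations) and, when ``outdir`` is given,
    writes the generated inputs, intermediate tables and ``report.json``.
    """
    cfg = demo_config(0)
    if config:
        cfg.update(config)
    seeds = _stage_seeds(cfg["seed"])
    offsets = {int(k): int(v) for k, v in cfg["offsets"].items()}

    annotations, truth = synthetic.generate_transcriptome(
        n_genes=cfg["n_genes"],
        seed=seeds[0],
        frac_polyadenylated=cfg["frac_polyadenylated"],
    )
    ann_by_id = {a.transcript_id: a for a in annotations}
    gene_ids = [a.gene_id for a in annotations]
    tx_lengths = np.asarray([a.transcript_length for a in annotations])

    abundance, te_undiff = synthetic.simulate_expression(
        cfg["n_genes"], seed=seeds[1],
        abundance_sigma=cfg["abundance_sigma"], te_sigma=cfg["te_sigma"],
    )
    shift_rng = np.random.default_rng(seeds[2])
    te_diff = te_undiff * shift_rng.lognormal(0.0, cfg["te_shift_sigma"], cfg["n_genes"])
    truth.extras["abundance"] = abundance
    truth.extras["te_undiff"] = te_undiff
    truth.extras["te_diff"] = te_diff
    truth.extras["offsets"] = {str(k): v for k, v in offsets.items()}

    # mRNA counts (3 replicates x 2 conditions) and TPM-based UTR selection
    mrna_samples = [f"mrna_{c}_{r}" for c in ("undiff", "diff") for r in (1, 2, 3)]
    mrna = synthetic.simulate_count_matrix(
        abundance, gene_ids, mrna_samples, cfg["n_mrna_reads"],
        dispersion=cfg["mrna_dispersion"], seed=seeds[3],
    )
    tpm = compute_tpm(mrna.mean(axis=1).to_numpy(), tx_lengths)
    tpm_by_tid = {a.transcript_id: t for a, t in zip(annotations, tpm)}
    utrs = select_analysis_utr3s(
        annotations, tpm_by_tid, tpm_min=cfg["tpm_min"], min_len=cfg["utr3_min_len"]
    )

    apa_set = synthetic.simulate_peaks(
        annotations, truth, "APA",
        n_replicates=cfg["n_replicates"], seed=seeds[4],
        apa_rate=cfg["apa_rate"], jitter_sd=cfg["jitter_sd"],
        dropout_rate=cfg["dropout_rate"],
    )
    clip_set = synthetic.simulate_peaks(
        annotations, truth, "CLIP",
        n_replicates=cfg["n_replicates"], seed=seeds[5],
        target_odds_ratio=cfg["target_odds_ratio"],
        clip_base_rate=cfg["clip_base_rate"], jitter_sd=cfg["jitter_sd"],
        dropout_rate=cfg["dropout_rate"],
    )
    association = coloc_stats.associate(utrs, apa_set, clip_set)

    # PAS statistics on reproducible CLIP peaks inside analysis UTRs
    from .peaklib import reproducible_peaks

    clip_repro = reproducible_peaks(clip_set)
    assigned = assign_peaks_to_utrs(clip_repro, utrs)
    pas_fraction, n_excl = pas_motif.peak_pas_fraction(assigned, flank=cfg["flank"])
    enrichment = pas_motif.pas_positional_enrichment(
        assigned, flank=cfg["flank"], n_shuffles=cfg["n_shuffles"], seed=seeds[6]
    )
    distances = pas_motif.terminal_distance_distribution(assigned)

    # terminal CLIP signal vs 3'-UTR length (independence check)
    clip_counts = synthetic.simulate_clip_utr3_counts(
        abundance, te_undiff, gene_ids, total_reads=cfg["n_clip_reads"], seed=seeds[7]
    )
    utr3_len = pd.Series(
        [a.utr3_len for a in annotations], index=pd.Index(gene_ids, name="gene_id")
    )
    length_check = coloc_stats.signal_vs_utr3_length(
        clip_counts.to_numpy(), utr3_len.to_numpy()
    )

    # ribosome profiling: footprints, metagene, occupancy window
    footprints = synthetic.simulate_footprints(
        annotations, abundance, te_undiff, offsets=offsets,
        n_reads=cfg["n_footprint_reads"], seed=seeds[8], sample="mono_undiff_1",
    )
    profile = riboprofile.metagene_profile(
        footprints, ann_by_id, anchor="start_codon", offsets=offsets,
        **cfg["metagene"],
    )
    occupancy = riboprofile.cds_occupancy_counts(
        footprints, ann_by_id, offsets=offsets, **cfg["occupancy_window"]
    )

    # TE table over two conditions, three NB replicates each
    rpf_samples = [f"rpf_{c}_{r}" for c in ("undiff", "diff") for r in (1, 2, 3)]
    rpf = pd.concat(
        [
            synthetic.simulate_count_matrix(
                abundance * te_undiff, gene_ids, rpf_samples[:3],
                cfg["n_rpf_reads"], dispersion=cfg["rpf_dispersion"], seed=seeds[9],
            ),
            synthetic.simulate_count_matrix(
                abundance * te_diff, gene_ids, rpf_samples[3:],
                cfg["n_rpf_reads"], dispersion=cfg["rpf_dispersion"], seed=seeds[10],
            ),
        ],
        axis=1,
    )
    conditions = {s: ("diff" if "_diff_" in s else "undiff") for s in mrna_samples + rpf_samples}
    te_table, te_excluded = quant.translation_efficiency(
        rpf, mrna, conditions, log2fc_conditions=("diff", "undiff")
    )

    # CLIP 3'-UTR RPKM vs footprint output and TE (trimmed Spearman)
    signal = quant.utr3_rpkm(
        clip_counts, utr3_len, library_size=float(clip_counts.sum()),
        min_len=cfg["utr3_min_len"],
    )
    shared = signal.index.intersection(te_table.index)
    rho_rpf, n_rpf = quant.spearman_trimmed(
        signal.loc[shared, "rpkm"], te_table.loc[shared, "mean_rpf_undiff"],
        trim_pct=cfg["trim_pct"],
    )
    rho_te, n_te = quant.spearman_trimmed(
        signal.loc[shared, "rpkm"], te_table.loc[shared, "te_undiff"],
        trim_pct=cfg["trim_pct"],
    )

    codon = codon_flatness_summary(profile)
    report = {
        "config": {k: v for k, v in cfg.items() if k != "offsets"},
        "n_analysis_utrs": len(utrs),
        "association": {
            "table": dict(zip("abcd", association.table.as_tuple())),
            "odds_ratio": association.odds_ratio,
            "p_value": association.p_value,
            "alternative": association.alternative,
        },
        "pas": {
            "peak_fraction_with_pas": pas_fraction,
            "n_peaks_excluded": n_excl,
            "empirical_p": enrichment.empirical_p,
            "n_peaks": enrichment.n_peaks,
            "median_terminal_distance_nt": float(np.median(distances)),
        },
        "length_independence": length_check,
        "metagene": {
            "n_genes": profile.n_genes,
            "codon_mean": codon["mean"],
            "codon_max_abs_dev": codon["max_abs_dev"],
        },
        "te": {
            "n_genes": int(len(te_table)),
            "n_excluded_zero_mrna": len(te_excluded),
            "median_te_undiff": float(te_table["te_undiff"].median()),
            "frac_te_unchanged": float(
                (te_table["log2fc_te"].abs() < 0.5).mean()
            ),
        },
        "correlations": {
            "clip_rpkm_vs_rpf_rho": rho_rpf,
            "clip_rpkm_vs_rpf_n": n_rpf,
            "clip_rpkm_vs_te_rho": rho_te,
            "clip_rpkm_vs_te_n": n_te,
        },
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        formats_io.write_fasta(
            {a.transcript_id: a.sequence for a in annotations}, outdir / "transcripts.fa"
        )
        formats_io.write_transcript_table(annotations, outdir / "transcripts.tsv")
        for peakset in (apa_set, clip_set):
            for label, peaks in zip(peakset.labels, peakset.replicates):
                formats_io.write_bed_peaks(peaks, outdir / f"{label}.bed")
        formats_io.write_bed_intervals(clip_repro, outdir / "CLIP_reproducible.bed")
        formats_io.write_footprint_table(footprints, outdir / "footprints.tsv")
        formats_io.write_count_matrix(mrna, outdir / "mrna_counts.tsv")
        formats_io.write_count_matrix(clip_counts.to_frame(), outdir / "clip_utr3_counts.tsv")
        formats_io.write_count_matrix(rpf, outdir / "rpf_counts.tsv")
        formats_io.write_count_matrix(occupancy, outdir / "occupancy_counts.tsv")
        te_table.to_csv(outdir / "te_table.tsv", sep="\t")
        riboprofile.profile_to_frame(profile).to_csv(
            outdir / "metagene_profile.tsv", sep="\t"
        )
        truth.to_json(outdir / "truth.json")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
    return report


def assign_peaks_to_utrs(peaks, utrs):
    """Pair each peak with the (unique) analysis UTR that contains it.

    Peaks not fully contained in any analysis UTR are dropped: the PAS
    geometry statistics are defined only for crosslink peaks inside the
    3'-UTR whose sequence is in hand.
    """
    by_chrom: dict[str, list] = {}
    for u in utrs:
        if u.utr3_interval is not None:
            by_chrom.setdefault(u.utr3_interval.chrom, []).append(u)
    for lst in by_chrom.values():
        lst.sort(key=lambda u: u.utr3_interval.start)
    assigned = []
    for peak in peaks:
        group = by_chrom.get(peak.chrom, [])
        starts = [u.utr3_interval.start for u in group]
        k = bisect.bisect_right(starts, peak.start)
        if k > 0:
            u = group[k - 1]
            iv = u.utr3_interval
            if peak.start >= iv.start and peak.end <= iv.end:
                assigned.append((peak, u))
    return assigned


def codon_flatness_summary(profile) -> dict:
    """Mean and max deviation of per-codon profile sums from 1.0.

    With the default offset map, the three 5'-end positions of the reads
    decoding codon c are {3c-16, 3c-15, 3c-14} relative to the start
    codon, so per-codon sums of the length-summed profile are expected to
    be 1.0 under uniform codon sampling.
    """
    pos_sums = profile.position_sums()
    lo = int(profile.positions[0])
    values = []
    c = 1
    while True:
        r0 = 3 * c - 16
        if r0 < lo:
            c += 1
            continue
        if 3 * c - 14 > int(profile.positions[-1]):
            break
        i0 = r0 - lo
        values.append(float(pos_sums[i0 : i0 + 3].sum()))
        c += 1
    values = np.asarray(values)
    return {
        "mean": float(values.mean()),
        "max_abs_dev": float(np.abs(values - 1.0).max()),
        "per_codon": values.tolist(),
    }
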