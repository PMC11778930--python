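"""Closed-loop calibration experiments on planted synthetic data.

Each experiment plants a known parameter with the generator, runs the
corresponding pipeline stage, and measures recovery.  These are the
package's validation experiments; the default problem sizes (5,000 UTRs
for association recovery, 200,000 reads for profiling and TE) are the
study conditions the generator emulates.

The association-recovery experiments use sparse peak margins (APA
reproducible-peak prevalence ~0.10 of analysis UTRs, marginal CLIP rate
0.05): reproducible peaks consistent across three replicates are a small
subset of expressed UTRs, and per-replicate dropout attenuates the
observed odds ratio more strongly at dense margins (a dropped APA peak
relabels its UTR as "CLIP only").
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import coloc_stats, quant, riboprofile, synthetic


def _calibration_transcriptome(n_utrs: int, seed: int):
    return synthetic.generate_transcriptome(n_genes=n_utrs, seed=seed)


def simulate_association_once(
    annotations,
    truth,
    target_odds_ratio: float,
    seed: int,
    dropout_rate: float = 0.05,
    apa_rate: float = 0.12,
    clip_base_rate: float = 0.05,
    jitter_sd: float = 2.0,
    n_replicates: int = 3,
) -> coloc_stats.AssociationResult:
    """One peak-simulation + association round on a fixed transcriptome."""
    truth.extras.pop("apa_present", None)
    apa = synthetic.simulate_peaks(
        annotations, truth, "APA", n_replicates=n_replicates, seed=seed,
        apa_rate=apa_rate, jitter_sd=jitter_sd, dropout_rate=dropout_rate,
    )
    clip = synthetic.simulate_peaks(
        annotations, truth, "CLIP", n_replicates=n_replicates, seed=seed + 1,
        target_odds_ratio=target_odds_ratio, clip_base_rate=clip_base_rate,
        jitter_sd=jitter_sd, dropout_rate=dropout_rate,
    )
    return coloc_stats.associate(annotations, apa, clip)


def odds_ratio_recovery(
    target_odds_ratios=(1.0, 2.0, 4.0, 8.0),
    n_utrs: int = 5000,
    n_sims: int = 200,
    dropout_rate: float = 0.05,
    seed: int = 0,
) -> dict[float, float]:
    """Median estimated odds ratio over seeded simulations, per planted OR.

    The transcriptome is fixed per planted value; each simulation re-draws
    peak presence, jitter and dropout.
    """
    out: dict[float, float] = {}
    for k, target in enumerate(target_odds_ratios):
        annotations, truth = _calibration_transcriptome(n_utrs, seed=seed + 7_000 + k)
        estimates = []
        for s in range(n_sims):
            res = simulate_association_once(
                annotations, truth, target,
                seed=seed + 2 * (k * n_sims + s), dropout_rate=dropout_rate,
            )
            estimates.append(res.odds_ratio)
        finite = [e for e in estimates if np.isfinite(e)]
        out[float(target)] = float(np.median(finite))
    return out


def null_pvalue_uniformity(
    n_runs: int = 500,
    n_utrs: int = 5000,
    dropout_rate: float = 0.05,
    seed: int = 0,
) -> dict:
    """KS distance of null (planted OR = 1) Fisher p-values from uniform."""
    annotations, truth = _calibration_transcriptome(n_utrs, seed=seed + 9_001)
    pvals = []
    for s in range(n_runs):
        res = simulate_association_once(
            annotations, truth, 1.0, seed=seed + 100_000 + 2 * s,
            dropout_rate=dropout_rate,
        )
        pvals.append(res.p_value)
    ks = stats.kstest(pvals, "uniform").statistic
    return {"ks_statistic": float(ks), "p_values": pvals}


def asite_and_metagene_recovery(
    n_genes: int = 500,
    n_reads: int = 200_000,
    seed: int = 0,
    offsets=riboprofile.DEFAULT_OFFSETS,
) -> dict:
    """Noiseless-generation recovery of A-site codons and metagene flatness.

    Returns the fraction of in-CDS reads whose frame-assigned A-site codon
    equals the generating codon, the per-codon flatness of the uniform
    metagene profile, and the max change of the profile after multiplying
    one gene's reads tenfold (expected 0: per-gene rescaling removes depth).
    """
    from .pipeline import codon_flatness_summary

    annotations, _truth = synthetic.generate_transcriptome(
        n_genes=n_genes, seed=seed, frac_long_cds=1.0
    )
    abundance, te = synthetic.simulate_expression(n_genes, seed=seed + 1)
    fp = synthetic.simulate_footprints(
        annotations, abundance, te, offsets=offsets, n_reads=n_reads, seed=seed + 2
    )
    ann_by_id = {a.transcript_id: a for a in annotations}
    utr5 = fp["transcript_id"].map({a.transcript_id: a.utr5_len for a in annotations})
    codon_hat = riboprofile.assign_a_sites(
        fp["five_prime_pos"].to_numpy(), utr5.to_numpy(), offsets
    )
    n_codons = fp["transcript_id"].map(
        {a.transcript_id: a.n_codons for a in annotations}
    ).to_numpy()
    in_cds = (codon_hat >= 0) & (codon_hat < n_codons)
    recovery = float(np.mean(codon_hat[in_cds] == fp["true_codon"].to_numpy()[in_cds]))

    profile = riboprofile.metagene_profile(fp, ann_by_id, offsets=offsets)
    flatness = codon_flatness_summary(profile)
    # sampling scatter of a per-codon sum: each passing gene contributes a
    # ~Poisson(scale_g) count weighted 1/scale_g, so Var ~ sum(1/scale_g)/n^2
    reads_in_cds = fp[in_cds].groupby("transcript_id").size()
    scales = (
        reads_in_cds / reads_in_cds.index.map({a.transcript_id: a.n_codons
                                               for a in annotations})
    )
    scales = scales[scales >= 1.0]
    flatness_sigma = float(np.sqrt((1.0 / scales).sum()) / len(scales))

    # tenfold depth change of the deepest gene must not move the profile
    top_gene = fp["transcript_id"].value_counts().idxmax()
    boosted = fp[fp["transcript_id"] == top_gene]
    fp_boosted = pd.concat([fp] + [boosted] * 9, ignore_index=True)
    profile_boosted = riboprofile.metagene_profile(fp_boosted, ann_by_id, offsets=offsets)
    depth_dev = float(np.abs(profile.matrix - profile_boosted.matrix).max())

    return {
        "asite_recovery_fraction": recovery,
        "flatness_mean": flatness["mean"],
        "flatness_max_abs_dev": flatness["max_abs_dev"],
        "flatness_sigma": flatness_sigma,
        "depth_invariance_max_dev": depth_dev,
        "n_metagene_genes": profile.n_genes,
        "per_codon": flatness["per_codon"],
    }


def te_recovery(
    n_genes: int = 1000,
    n_reads_per_assay: int = 200_000,
    seed: int = 0,
) -> dict:
    """Spearman correlation between planted and estimated TE.

    RPF counts come from simulated footprints tallied through the CDS
    occupancy window; mRNA counts are negative binomial.
    """
    annotations, _truth = synthetic.generate_transcriptome(
        n_genes=n_genes, seed=seed, frac_long_cds=1.0
    )
    abundance, te = synthetic.simulate_expression(n_genes, seed=seed + 1)
    fp = synthetic.simulate_footprints(
        annotations, abundance, te, n_reads=n_reads_per_assay, seed=seed + 2,
        sample="rpf_1",
    )
    ann_by_id = {a.transcript_id: a for a in annotations}
    rpf = riboprofile.cds_occupancy_counts(fp, ann_by_id)
    gene_ids = [a.gene_id for a in annotations]
    mrna = synthetic.simulate_count_matrix(
        abundance, gene_ids, ["mrna_1"], n_reads_per_assay,
        dispersion=0.05, seed=seed + 3,
    )
    conditions = {"rpf_1": "c", "mrna_1": "c"}
    te_table, _excluded = quant.translation_efficiency(rpf, mrna, conditions)
    true_te = dict(zip(gene_ids, te))
    truth_vec = np.asarray([true_te[g] for g in te_table.index])
    rho = stats.spearmanr(truth_vec, te_table["te_c"].to_numpy()).statistic
    return {"spearman": float(rho), "n_genes": int(len(te_table))}
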