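"""Normalization, translation efficiency, 3'-UTR CLIP signal, correlations.

Size factors follow the median-of-ratios construction: for each sample,
the median over genes (restricted to genes with strictly positive counts
in every sample) of that sample's count divided by the gene's geometric
mean across samples, with the geometric mean computed in log space.
Translation efficiency is the ratio of normalized ribosome-footprint to
normalized mRNA condition means; the assays are normalized independently.
Dispersion modelling, shrinkage and differential testing are deliberately
out of scope — only normalization, means, and fold changes.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one per sample (column).

    sf_j = median over all-positive genes g of K_gj / gmean_g, with
    gmean_g the geometric mean of gene g across samples.  Raises when no
    gene is positive in every sample.
    """
    if counts.index.duplicated().any() or counts.columns.duplicated().any():
        raise ValueError("duplicate gene or sample identifiers")
    values = counts.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("negative counts")
    all_positive = (values > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError("no gene with strictly positive counts in all samples")
    logk = np.log(values[all_positive])
    log_gmean = logk.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logk - log_gmean, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    return counts / size_factors_median_of_ratios(counts)


def translation_efficiency(
    rpf: pd.DataFrame,
    mrna: pd.DataFrame,
    conditions: Mapping[str, str],
    log2fc_conditions: tuple[str, str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene TE table from RPF and mRNA count matrices.

    ``conditions`` maps sample name -> condition label for both assays.
    Each assay is normalized independently by median-of-ratios; condition
    means are taken over replicates; TE_cond = mean RPF / mean mRNA.  When
    ``log2fc_conditions = (num, den)`` is given, log2 fold changes of RPF,
    mRNA and TE (num over den) are added.  Genes whose mRNA mean is zero
    in any condition are excluded from the table and returned separately.
    """
    genes = rpf.index.intersection(mrna.index)
    if len(genes) == 0:
        raise ValueError("empty shared gene set between RPF and mRNA matrices")
    rpf_n = normalize_counts(rpf.loc[genes])
    mrna_n = normalize_counts(mrna.loc[genes])

    def condition_means(norm: pd.DataFrame) -> pd.DataFrame:
        cols = {}
        for cond in sorted(set(conditions[s] for s in norm.columns)):
            samples = [s for s in norm.columns if conditions[s] == cond]
            cols[cond] = norm[samples].mean(axis=1)
        return pd.DataFrame(cols)

    rpf_means = condition_means(rpf_n)
    mrna_means = condition_means(mrna_n)
    zero_mrna = (mrna_means == 0).any(axis=1)
    excluded = genes[zero_mrna].tolist()
    keep = genes[~zero_mrna.to_numpy()]

    table = pd.DataFrame(index=keep)
    for cond in rpf_means.columns:
        table[f"mean_rpf_{cond}"] = rpf_means.loc[keep, cond]
        table[f"mean_mrna_{cond}"] = mrna_means.loc[keep, cond]
        table[f"te_{cond}"] = rpf_means.loc[keep, cond] / mrna_means.loc[keep, cond]
    if log2fc_conditions is not None:
        num, den = log2fc_conditions
        with np.errstate(divide="ignore", invalid="ignore"):
            table["log2fc_rpf"] = np.log2(rpf_means.loc[keep, num] / rpf_means.loc[keep, den])
            table["log2fc_mrna"] = np.log2(mrna_means.loc[keep, num] / mrna_means.loc[keep, den])
            table["log2fc_te"] = np.log2(table[f"te_{num}"] / table[f"te_{den}"])
    table.index.name = "gene_id"
    return table, excluded


def utr3_rpkm(
    clip_counts: pd.Series,
    utr3_len: pd.Series,
    library_size: float,
    min_len: int = 50,
) -> pd.DataFrame:
    """3'-UTR CLIP RPKM per gene: count * 1e9 / (library_size * utr3_len).

    Genes whose 3'-UTR is not strictly longer than ``min_len`` nt are
    excluded (not an error).
    """
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    genes = clip_counts.index.intersection(utr3_len.index)
    lens = utr3_len.loc[genes]
    keep = lens > min_len
    genes = genes[keep.to_numpy()]
    rpkm = clip_counts.loc[genes] * 1e9 / (library_size * utr3_len.loc[genes])
    out = pd.DataFrame(
        {
            "count": clip_counts.loc[genes],
            "utr3_len": utr3_len.loc[genes],
            "rpkm": rpkm,
        }
    )
    out.index.name = "gene_id"
    return out


def spearman_trimmed(
    x: Sequence[float], y: Sequence[float], trim_pct: float = 99.0
) -> tuple[float, int]:
    """Spearman rho after dropping pairs whose y exceeds its percentile.

    The percentile uses linear interpolation between order statistics and
    only the y variable is trimmed.  Average ranks break ties.  Raises when
    fewer than 3 pairs survive.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired vectors required")
    cutoff = np.percentile(y, trim_pct)
    keep = y <= cutoff
    n_used = int(keep.sum())
    if n_used < 3:
        raise ValueError(f"need >= 3 pairs after trimming, got {n_used}")
    rho = stats.spearmanr(x[keep], y[keep]).statistic
    return float(rho), n_used


def top_n_intersection(
    ranked_lists: Sequence[Sequence[str]], n: int
) -> tuple[set, dict[tuple[int, int], int]]:
    """Intersection of the top-n entries of rank-ordered, duplicate-free lists.

    Returns the common set across all lists plus each pairwise common
    count (keyed by list-index pair).
    """
    if len(ranked_lists) < 2:
        raise ValueError("need at least two ranked lists")
    tops = []
    for i, lst in enumerate(ranked_lists):
        lst = list(lst)
        if len(set(lst)) != len(lst):
            raise ValueError(f"list {i} contains duplicates")
        tops.append(set(lst[:n]))
    common = set.intersection(*tops)
    pairwise = {
        (i, j): len(tops[i] & tops[j]) for i, j in combinations(range(len(tops)), 2)
    }
    return common, pairwise
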