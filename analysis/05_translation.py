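#!/usr/bin/env python
"""Translation efficiency and CLIP-signal correlations.

Reads the RPF and mRNA count matrices, computes the median-of-ratios
normalized TE table with differentiated-vs-undifferentiated log2 fold
changes, then correlates 3'-UTR CLIP RPKM with footprint output and
with TE (trimmed Spearman).  Writes results/te_table.tsv and
results/correlations.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from utrterm import formats_io, quant


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("scratch/demo_data"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    rpf = formats_io.read_count_matrix(args.data / "rpf_counts.tsv")
    mrna = formats_io.read_count_matrix(args.data / "mrna_counts.tsv")
    conditions = {s: ("diff" if "_diff_" in s else "undiff") for s in
                  list(rpf.columns) + list(mrna.columns)}
    table, excluded = quant.translation_efficiency(
        rpf, mrna, conditions, log2fc_conditions=("diff", "undiff")
    )
    frac_unchanged = float((table["log2fc_te"].abs() < 0.5).mean())
    print(f"TE table: {len(table)} genes ({len(excluded)} excluded, zero mRNA)")
    print(f"fraction with |log2FC TE| < 0.5: {frac_unchanged:.2f}")

    annotations = formats_io.read_transcript_table(args.data / "transcripts.tsv")
    utr3_len = pd.Series({a.gene_id: a.utr3_len for a in annotations})
    clip = formats_io.read_count_matrix(args.data / "clip_utr3_counts.tsv").iloc[:, 0]
    signal = quant.utr3_rpkm(clip, utr3_len, library_size=float(clip.sum()))
    shared = signal.index.intersection(table.index)
    rho_rpf, n1 = quant.spearman_trimmed(
        signal.loc[shared, "rpkm"], table.loc[shared, "mean_rpf_undiff"]
    )
    rho_te, n2 = quant.spearman_trimmed(
        signal.loc[shared, "rpkm"], table.loc[shared, "te_undiff"]
    )
    print(f"Spearman(CLIP 3'-UTR RPKM, mean RPF) = {rho_rpf:.3f} (n={n1})")
    print(f"Spearman(CLIP 3'-UTR RPKM, TE)       = {rho_te:.3f} (n={n2})")

    Path("results").mkdir(exist_ok=True)
    table.to_csv("results/te_table.tsv", sep="\t")
    with open("results/correlations.json", "w") as fh:
        json.dump(
            {"clip_rpkm_vs_rpf_rho": rho_rpf, "n_rpf": n1,
             "clip_rpkm_vs_te_rho": rho_te, "n_te": n2,
             "frac_te_unchanged": frac_unchanged,
             "n_te_genes": len(table)},
            fh, indent=1,
        )


if __name__ == "__main__":
    main()
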