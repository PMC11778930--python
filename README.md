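# utrterm

Analysis of translation-initiation-factor CLIP crosslinking at 3'-UTR
termini: colocalization with polyadenylation sites, PAS motif geometry,
and ribosome-profiling quantification.

## The problem

CLIP experiments on the multisubunit initiation factor eIF3 show
crosslink peaks concentrated at the *ends* of mRNA 3'-UTRs, immediately
upstream of the poly(A) tail, where the polyadenylation signal (PAS,
canonically AAUAAA) sits.  Testing what that means requires linking
three transcriptome-wide measurements on the same cells:

1. **CLIP peaks** (replicated) — where the factor crosslinks;
2. **APA-seq peaks** (replicated) — where poly(A) addition actually
   occurs, i.e. the termini of expressed 3'-UTR isoforms;
3. **Ribosome profiling + RNA-seq** — how actively each mRNA is
   translated (footprint counts, translation efficiency).

`utrterm` implements that integrative analysis as a tested library for
people working with CLIP/3'-end-seq/profiling data: reproducible-peak
derivation, the colocalization statistic, PAS hexamer scanning with a
shuffle null, P1-nuclease footprint processing (monosome 32–40 nt,
disome split at 60 nt; frame-based A-site offsets), median-of-ratios
normalization and TE, plus a synthetic-data generator with planted
ground truth so that every stage can be validated end to end without
any sequencing download.

## The core statistic

Over the analysis set of 3'-UTRs (expressed at TPM > 1, longer than
50 nt, genomically non-overlapping), each UTR is scored for presence of
a reproducible peak from each assay (a peak present, at base level, in
**all** replicates).  With

|                | CLIP + | CLIP − |
|----------------|--------|--------|
| **APA +**      |   a    |   b    |
| **APA −**      |   c    |   d    |

the association is summarized by the sample odds ratio `OR = ad/bc` and
the two-sided Fisher exact p-value, computed with exact integer
arithmetic (hypergeometric table weights as big-integer binomials, exact
tie comparison, rational p rounded to float only at the end).

Around it: `find_pas` / `peak_pas_fraction` / `pas_positional_enrichment`
(fraction of peaks with AAUAAA within a ±25 nt flank, against a
width-preserving within-UTR shuffle null), `terminal_distance_distribution`
(strand-aware distance from peak 3' edge to the UTR terminus),
`metagene_profile` (per-gene rescaled, length-stratified), A-site codon
assignment `5' end + offset[frame]` with default offsets {0:15, 1:16,
2:17}, the +15th→−10th codon occupancy window, and `TE = normalized
RPF / normalized mRNA` per condition.

## Worked example

```sh
python analysis/01_simulate.py --seed 1     # writes scratch/demo_data/
python analysis/02_colocalization.py --seed 1 --n-sims 10
```

prints

```
2000 analysis UTRs; table (a,b,c,d)=(26,145,64,1765)
odds ratio 4.945, two-sided Fisher p 6.78e-09
planted-OR recovery grid (10 sims each) ...
  planted OR 1: median estimate 1.064
  planted OR 2: median estimate 1.920
  planted OR 4: median estimate 3.511
  planted OR 8: median estimate 7.194
```

The demo plants an odds ratio of 5.6 between APA-peak and CLIP-peak
presence across 2,000 UTRs; the pipeline recovers a strongly significant
positive association (the estimate sits somewhat below the planted value
because per-replicate peak dropout attenuates the observed table — see
`docs/methods.md`).  The remaining drivers continue the study:
`03_pas_motif.py` (92% of reproducible CLIP peaks carry AAUAAA within
±25 nt, shuffle p at its minimum attainable value 1/1001, median peak
edge 16 nt from the UTR terminus), `04_ribosome_profiling.py` (metagene
flat at 0.996 under uniform codon sampling; 183,453 of 200,000
footprints inside the occupancy window), and `05_translation.py`
(Spearman of CLIP 3'-UTR RPKM 0.766 with footprint counts vs 0.487 with
TE — terminal CLIP signal tracks translational *output*, not
efficiency).

The same steps are available as a CLI (`utrterm simulate|coloc|pasmotif|
riboprof|te|correlate|run`) for file-based use.

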