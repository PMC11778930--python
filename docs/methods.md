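# Methods

This note documents the statistical procedures, the synthetic-data
model behind the validation experiments, and the design choices made
where the underlying analyses admit more than one reasonable reading.

## Coordinates and formats

All intervals are 0-based half-open internally, so BED I/O is the
identity on coordinates.  Transcript annotations come from a simplified
TSV — one single-isoform transcript per row with 5'-UTR/CDS/3'-UTR
lengths and the genomic extent of the 3'-UTR — rather than GTF exon
chains: the analyses need only segment lengths and the 3'-UTR interval,
and multi-exon 3'-UTR stitching is out of scope.  Footprint alignments
are in transcript coordinates, as transcriptome aligners produce them.

## Reproducible peaks

A genomic base is reproducible when it is covered by at least one peak
in every replicate of an assay; reproducible peaks are the maximal
contiguous runs of such bases.  Base-level intersection was chosen over
pairwise peak matching because it is deterministic, order-independent,
and equivalent to the intersect-then-merge idiom of interval toolkits;
with a single replicate it reduces to merging.  Peak caller scores are
not propagated: the downstream statistic is presence/absence.
Consequences: adding a replicate can only shrink the reproducible base
set, and per-replicate dropout at rate d retains a planted peak with
probability (1−d)^n for n replicates.

## Analysis 3'-UTR selection

A transcript enters the colocalization analysis when its TPM is
strictly greater than 1, its 3'-UTR is strictly longer than 50 nt, and
its 3'-UTR interval overlaps (≥1 base, strand ignored by default) no
other candidate's.  Every member of an overlapping cluster is removed —
not keep-the-longest — because overlapping 3'-UTR isoforms make
peak-to-isoform attribution ambiguous in both directions; dropping the
cluster removes the ambiguity symmetrically.  A same-strand-only
overlap mode is available as a flag.

## Colocalization statistic

Each analysis UTR is scored for reproducible APA-peak and CLIP-peak
presence (≥1 overlapping base; a peak abutting the UTR end does not
count, by half-openness).  The 2×2 table is summarized by the plain
sample odds ratio ad/bc — no Haldane/continuity correction, +∞ when
bc = 0 with ad > 0, undefined (NaN) when both products vanish — and by
Fisher's exact test with margins fixed.

The Fisher implementation is exact-integer: table weights
C(r1, x)·C(r2, k−x) are big integers, the two-sided rule sums the
probabilities of all tables whose weight is ≤ the observed weight with
an *integer* comparison (no floating-point tie epsilon), and the p-value
is an exact rational converted to float at the end.  Two-sided is the
default; `greater`/`less` are available.  Exactness matters here: at
realistic table sizes the p-values of interest are far below double
rounding noise (the demo regularly produces p < 1e-40), and float tie
comparison is the classic failure mode of two-sided Fisher
implementations.

## PAS motif statistics

Motif discovery is out of scope; the scan targets a configured hexamer
set, default {AAUAAA} with {AAUAAA, AUUAAA} available.  T≡U, N never
matches, overlapping occurrences all count.  A peak "carries" a PAS
when a motif start lies in [peak_start − flank, peak_end + flank)
clipped to the UTR, in UTR-local (5'→3') coordinates; flank defaults to
25 nt.  The flank stands in for the window a de-novo motif finder would
use around crosslink sites — that window is not recoverable from the
upstream tooling, so the absolute fractions depend on this convention.

The enrichment null re-draws each peak's start uniformly within its own
UTR, preserving peak width and per-UTR peak count, so sequence
composition and UTR length are controlled; cross-UTR shuffling would
confound both.  empirical_p = (1 + #{null ≥ observed})/(n_shuffles + 1),
n_shuffles ≥ 100 required, deterministic given the seed; the minimum
attainable p is 1/(n_shuffles + 1).

Terminal distance is strand-aware: on '+' the distance from peak end to
the UTR interval end; on '−' from interval start to peak start.

## Ribosome profiling

Footprint classes follow P1-nuclease length signatures: monosome
libraries yield 32–40 nt monosome footprints (outside: unassigned);
disome libraries split at 60 nt into sub-disome (<60) and true disome
(≥60).

A-site assignment: frame = (5'end − utr5_len) mod 3; A-site nucleotide
= 5'end + offset[frame]; codon = floor((A-site − utr5_len)/3), which
may be negative (5'-UTR) or beyond the stop (3'-UTR) and is returned
as-is.  The default offset map {0:15, 1:16, 2:17} maps the three
5'-end frames of one footprint population onto a single codon; the
exact offsets of any given protocol belong to its calibration, so the
map is required, overridable configuration with this documented
default.

Occupancy counting uses the read's A-site codon, not the read's span:
a read counts for its gene iff its A-site codon c (1-based) satisfies
15 ≤ c ≤ n_codons − 10.  Span-based exclusion would make the count
depend on read length; A-site-based exclusion is deterministic per
read and standard for occupancy work.  A uniform 1-read-per-codon
100-codon CDS yields exactly 76 counted reads.

Metagene profiles: genes pass with ≥50 nt 5'-UTR, ≥450 nt CDS, ≥50 nt
3'-UTR and mean CDS reads per codon ≥ 1 (mean-based, not
every-codon-covered — the latter would exclude nearly everything at
moderate depth).  Per passing gene, scale = CDS-mapped reads / n_codons;
each read contributes 1/scale at (length, 5'end − anchor); cells are
summed and divided by the number of passing genes.  Position 0 is the
first base of the start (or stop) codon and positions refer to read 5'
ends (3'-end anchoring is a flag).  This makes the profile exactly
depth-invariant per gene: multiplying one gene's reads by any constant
changes nothing (verified to 1e-16).  Length bins (e.g. 58–60 nt) sum
rows and must not overlap.

## Normalization, TE, correlations

Size factors are median-of-ratios: over genes with strictly positive
counts in every sample, sf_j = median_g K_gj / gmean_g, with the
geometric mean computed in log space.  Dispersion estimation, GLM
fitting and shrinkage are deliberately not implemented — only
normalization, condition means and fold changes.  RPF and mRNA
matrices are normalized independently; TE = mean normalized RPF / mean
normalized mRNA per condition; genes with zero mRNA mean are excluded
and reported.  TE is therefore defined up to a global scale shared by
all genes.

3'-UTR CLIP signal is RPKM = count·1e9/(library·utr3_len), genes with
3'-UTR ≤ 50 nt excluded.  Trimmed Spearman drops pairs whose y exceeds
the 99th percentile of y (linear interpolation between order
statistics); only the y variable (TE) is trimmed; ties get average
ranks.  Ranked-list comparison truncates each duplicate-free list to
its top n and reports the full and pairwise intersections.

## Synthetic-data model

The generator is the package's study stand-in; its defaults are the
conditions under which the validation experiments run.

**Transcriptome.** Single-isoform transcripts; 5'-UTR lognormal around
120 nt (clipped 20–600), CDS a 0.85/0.15 mixture of 450–2700 nt and
102–447 nt (multiples of 3, so metagene filters have both passers and
failers), 3'-UTR lognormal around 300 nt (clipped 60–2000).  85% of
transcripts are polyadenylated and receive one AAUAAA whose motif ends
10–40 nt upstream of the 3' terminus; the rest (histone-like) get none.
3'-UTR intervals are placed non-overlapping along one chromosome with
random strand.  Sequences are uniform-composition; chance AAUAAA hits
occur at the expected ~1/4^6 per position and are part of the
background the statistics must tolerate.

**Peaks.** APA peaks sit at the PAS of polyadenylated UTRs, each
detected with probability `apa_rate` (finite 3'-end-seq depth).  CLIP
presence per UTR is Bernoulli with log-odds shifted by log(target OR)
on APA-present UTRs, with the APA-negative rate solved so the marginal
CLIP rate equals `clip_base_rate`.  Association is planted at the
presence/absence level because that is the level of the downstream
statistic.  Each replicate realizes present peaks with rounded-normal
jitter (sd 2 nt, clipped into the UTR) and independent dropout.

**Footprints.** Per-gene read mass ∝ abundance × TE (abundance
lognormal σ=1, TE lognormal σ=0.8); A-site codon uniform over the CDS;
5' end placed at codon_start + ((f + offset_f) mod 3) − offset_f for a
uniform frame f, which frame-based assignment inverts exactly — the
generator is the literal inverse of the A-site mapper.  Monosome
lengths: triangular on 32–40 nt; disome: 40% sub-disome (45–59 nt),
60% true disome (60–75 nt) — generator defaults, not measured claims.
mRNA counts are gamma-Poisson (NB) with mean ∝ abundance and dispersion
0.05; CLIP 3'-UTR counts track (abundance·TE)^0.8 with lognormal noise,
planting a stronger correlation with footprint output than with TE.

**What the generator does not emulate:** read sequences and sequencing
error, crosslink-induced truncations/mutations, UMI/ligation artifacts,
multi-isoform APA within a gene (two same-gene transcripts with
different 3'-UTR lengths emulate it at the annotation level), non-uniform
codon dwell times, and contaminant RNA classes.  Passing tests
demonstrate correctness of the statistics under this model, not
robustness to those artifacts.

## Odds-ratio recovery and dropout attenuation

With three replicates and per-replicate dropout d = 0.05, a planted
peak survives base-intersection with probability 0.95³ ≈ 0.857.
Independent thinning of both assays biases the *observed* odds ratio
toward 1: a UTR whose APA peak dropped but whose CLIP peak survived is
tabulated as "CLIP only", contaminating the APA-negative margin with
APA-positive UTRs.  The contamination fraction is
p_APA(1−q)/(1−p_APA·q) (q = 0.857), so attenuation grows with APA
prevalence.  The recovery experiments therefore run at sparse margins —
APA prevalence ≈ 0.10 of analysis UTRs (frac_polyadenylated 0.85 ×
apa_rate 0.12), marginal CLIP rate 0.05 — which model the prevalence of
*reproducible* peaks within the analysis UTR set rather than the
chemistry of polyadenylation (nearly all mRNAs are polyadenylated;
far fewer carry a peak called consistently in all three replicates of
either assay).  At these margins the analytic expectation of the
observed OR at planted OR = 8 is ≈ 7.06 (−12%); at planted 1, exactly 1.
The demo pipeline (planted OR 5.6, denser margins) shows the same
attenuation (≈ 4.9 observed), which is reported as-is rather than
corrected: the package estimates the association among observed
reproducible peaks, as the real analysis does.

Null calibration: with planted OR = 1 the two-sided exact p-values over
500 seeded runs are approximately uniform (KS ≈ 0.08); exact Fisher p
is slightly super-uniform by discreteness, which is the expected
conservative direction.

## Problem sizes and numerical choices

Validation experiment sizes — 5,000 UTRs × 200 simulations per planted
OR, 500 null runs, 200k footprints over 500 genes, 1,000 genes × 200k
reads per assay for TE — were chosen so that binomial/rank noise is
well below the effect sizes being checked while the whole suite stays
interactive.  Metagene flatness is judged against its analytic sampling
scatter (per-codon variance ≈ Σ_g 1/scale_g / n_genes²).  Degenerate
inputs fail loudly: all-zero counts (TPM), no all-positive gene (size
factors), empty gene intersection (TE), n < 3 pairs (correlations),
zero passing genes (metagene, with the filter attrition listed).
Spearman on constant vectors returns NaN rather than raising, because a
constant signal is an informative experimental outcome.

## Known limitations

Single-isoform transcript model; genome-coordinate peaks but
transcript-coordinate footprints (no liftover between them); no
differential-TE inference (fold changes only, no dispersion model or
tests); PAS fractions depend on the flank convention; the odds-ratio
estimator is not corrected for replicate dropout attenuation.
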