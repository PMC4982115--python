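# Methods

`olfscreen` re-implements, as a tested pipeline over synthetic data with
planted ground truth, the analysis design of a bulk-RNAseq study of human
olfactory epithelium (OE): a handful of OE biopsies compared against one
respiratory-epithelium sample and a panel of control tissues, with a
companion mouse OE study wired through an ortholog map. This note records
the models, the parameter choices, and what the synthetic setting does and
does not establish.

## Expression conventions

Expression is FPKM in genes x samples tables. Zero FPKM values are floored
to 0.003 immediately after loading (before any log transform), so log10 is
finite everywhere downstream; the floor is a configuration parameter of
`io.apply_fpkm_floor`. Genomic intervals are 0-based half-open internally;
GTF I/O converts at the boundary (GTF is 1-based closed on disk). All
readers reject malformed input (duplicate gene ids, non-numeric or missing
cells, strand-inconsistent transcripts) with located errors.

## Overexpression screen

Counts of uniquely mapped reads are normalized with median-of-ratios size
factors (rescaled to geometric mean 1). Per-gene dispersion is a
method-of-moments estimate, `alpha = max(0, (var - mean)/mean^2)` on
normalized counts, pooled within groups and averaged. By default each
gene's dispersion is floored at the across-gene median ("maximum" sharing):
at a handful of samples per group the raw moment estimate is noisy, and its
underestimates make the exact test anti-conservative, while the max-sharing
floor keeps the null rejection rate near nominal (the calibration test and
the acceptance script measure it on a 4-vs-16, alpha = 0.1 null).
`sharing="none"` recovers the raw estimates.

Significance is an exact conditional negative-binomial test on the two
group totals: conditional on K = K_A + K_B, all splits (a, K-a) with
probability not exceeding the observed split's are summed, with
K_A ~ NB(q0*S_A, alpha/n_A) (q0 the pooled normalized mean, S_A the
size-factor sum). Computation is in log space (no overflow for totals up to
10^6). At alpha = 0 this is exactly the Poisson-conditional binomial test,
which is the oracle used in the tests. No multiple-testing correction is
applied by default, mirroring the fixed p < 0.001 rule; a
Benjamini–Hochberg q-value column is available but off by default.

A non-OR gene is called overexpressed when its FPKM fold change
(mean OE / mean controls, floored values) is >= 6 **and** p < 0.001, or is
rescued by a significantly overexpressed mouse ortholog provided the human
fold exceeds 6. Afterwards a retained gene is relabelled
`respiratory_filtered` when the respiratory sample carries more than 0.1 of
its mean OE expression (contamination filter; disabled with a warning if no
respiratory sample is present). Retained genes are split into evidence
class A (literature hits >= 1, the threshold is configurable) and B.
Fold changes for cross-species family comparisons can be restricted to the
control tissues shared by both studies (adipose, brain, heart, kidney,
liver, lung, testis).

## OR repertoire statistics

A gene is "expressed" at FPKM >= 0.01 in at least one sample of the tissue
group; per-gene expression is otherwise summarized as the mean across the
group's samples. Intact-vs-pseudogene comparisons use the two-sample
Kolmogorov–Smirnov test on per-gene mean FPKM; reported SDs are population
SDs (descriptive). The skew of the rank curve is summarized by the
half-fraction: the smallest k/n whose top-k genes hold >= 50% of the summed
expression, with the discrete (no interpolation) definition and FPKM ties
broken by gene id for determinism. The class I/II contrast is reported both
as a 2x2 chi-square on expressed counts (no continuity correction; flagged
unreliable when an expected cell is < 1 or a margin is empty) and as a KS
test on levels, because the published analysis does not pin down which
contrast was tested. The functionality-score association splits OR genes at
the median score and applies a two-sample KS to the two halves' expression;
the median split is our documented choice. Every repertoire operation can
be rerun on the catalog stripped of segregating-pseudogene loci
(`rerun_excluding_segregating`) as a sensitivity analysis.

## Inter-individual resampling test

For a pair of OE samples, the observed statistic is the Pearson correlation
of log10 FPKM over the OR set. The null is built from control gene sets
matched on reference expression — the mean log10 FPKM over the two compared
samples (the matching covariate is our documented choice; per-sample
matching is a config away). The sampler cuts the target distribution into
20 quantile bins, draws exactly the target's per-bin counts from the pool
(deterministic quota), and accepts a proposal when a two-sample KS against
the target gives p > 0.05; the one-sided empirical p uses the add-one
convention, p = (1 + #{null r <= observed r})/(n + 1), reported as
"< 1/(n+1)" when the count is zero. The default pool is all non-OR genes
expressed (>= 0.01 FPKM) in both samples.

A caveat: the null distribution is not exactly invariant to the bin count —
finer stratification matches the target realization more tightly, which a
KS test on a few hundred null draws can occasionally detect. The
deterministic quota minimizes this; the property test checks stability at a
fixed seed.

## Transcript curation and structure

Curation applies, in order: (1) drop assembler class codes x, s, p
(antisense / run-on artifacts), (2) drop transcripts under 1.0 FPKM,
(3) drop isoforms under 0.15% of their gene's major isoform (the printed
threshold taken literally — 0.0015 — though configurable, as it is
unusually permissive). Each removed model carries its first triggering
reason; the output is order-stable.

Structure statistics decompose a transcript into 5'UTR / CDS / 3'UTR in
transcript orientation, with the exact identity utr5 + cds + utr3 =
transcript length for functional models. The TSS is the 5'-most transcribed
base (smallest exon start on +, largest exon end - 1 on -). A transcript is
**aberrant** when its exon union excludes the initiating codon's first base
(splice-driven pseudogenization despite an intact genomic ORF); a
transcript that retains the start but splices out an internal CDS chunk is
flagged separately as `cds_incomplete` (internal disruption) rather than
aberrant. Genes are classed all_functional / mixed / all_aberrant from
their isoforms' flags.

## Promoter profiling

Promoter windows span [-750, +250) around each transcript's TSS; within a
gene, windows are retained greedily in descending transcript FPKM order and
a candidate is dropped when it overlaps a retained window by >= 500 bp.
Motifs are position weight matrices scored as log2 odds against a
background composition; unknown bases contribute 0. The default scan
threshold is 80% of the maximal PWM score. Hits are anchored at their
5'-most matching base in promoter orientation; offsets count bp upstream of
the TSS (TSS base = offset 0) and are binned over a 4 kb upstream window.
Motif over-representation versus background promoters is a Fisher exact
test on windows-with->=1-hit counts — an open, oracle-verifiable
replacement for proprietary TFBS-library statistics; equivalence with any
proprietary enrichment statistic is not claimed. The bundled
`ebf_like_pwm()` is a synthetic 10-bp early-B-cell-factor-like model
(consensus TCCCNNGGGA) used by the simulator and the examples.

## The synthetic study generator

The generator's defaults encode the study conditions: 4 OE samples, 1
respiratory sample, 16 human control tissues (mouse: 3 OE samples, 11
control tissues, no respiratory sample); 391 intact and 466 pseudogene OR
loci at full scale; intact OR median 0.1 FPKM with a log10(4) gap to
pseudogenes; OR gene-level log10 sd 0.71 in human — a lognormal Lorenz
curve then puts ~5% of genes over half the summed expression — and 0.40 in
mouse (~18%); silent fractions 0.10/0.40 (≈90%/60% expressed); 50 planted
fold-8 overexpressed genes plus 10 respiratory contaminants leaking half
their OE level into the respiratory sample; NB dispersion 0.1 with ~30
reads per FPKM unit.

Per-sample noise follows the canonical RNA-seq structure: a technical
component with variance ~ 1/(reads_per_fpkm * FPKM) on the log scale, a
biological floor of 0.12 log10, and — for OR genes only — extra
inter-individual variability sized toward a between-OE-sample correlation
of 0.35 (capped at 0.6 log10 so linear-scale moments stay finite-sample
stable). All multiplicative noise is mean-one, so planted group-mean fold
ratios are unbiased. Control tissues receive per-gene multiplicative
tissue effects, centered so the across-control mean equals the baseline:
most genes are broad (0.15 log10), a 25% minority is strongly
tissue-specific (1.0 log10); planted olfactory-specific genes are flat
across controls. Counts are Gamma–Poisson around each sample's FPKM
realization. A dedicated pair simulator (`simulate_sample_pair`)
constructs two-sample datasets with exact target correlations (0.35 vs
0.9) for the resampling test's calibration and power studies.

The transcript generator plants OR-like architectures — 0–3 short 5'
non-coding exons, one long last exon holding the whole 940 bp ORF plus a
3'UTR of ~2.8 kb — with known curation outcomes (low-FPKM, low
isoform-fraction, bad class-code isoforms) and aberrant isoforms that start
downstream of the ORF start. The promoter generator plants one PWM-sampled
motif instance per promoter at a uniform offset inside 100–300 bp upstream
of the TSS on an i.i.d. background of stated GC content.

What the generator does **not** emulate: zonal anatomy of the epithelium,
cell-type composition, genuine genome sequence, read-level artifacts,
between-gene correlation, and ortholog-pair expression correlation. Passing
tests therefore establish the pipeline's statistical and algorithmic
correctness under a faithful study geometry — not that the original
biological percentages are recovered, which would require the original
reads.

## Problem sizes and determinism

The analysis scripts and acceptance runs use a 2,000–6,000 gene repertoire
(full scale at 16k genes changes nothing structurally), 10,000 resampling
iterations where the resampling test is the object of study, and 200
iterations per dataset in the 500-dataset calibration studies. All
randomness flows from a single master seed through documented per-stage
substreams (`seed`, `seed+1`, ... in `scripts/acceptance.py`; stage
offsets in the pipeline), and reruns with the same configuration are
byte-identical for every deterministic stage.

## Known limitations

- The exact conditional NB test approximates each group total as a single
  NB variable (exact for equal size factors; an approximation otherwise).
- The respiratory filter uses the single respiratory sample as-is; with no
  such sample the filter is disabled, not imputed.
- The matched sampler can fail loudly (with the proposal count) when the
  pool cannot cover the target distribution; it does not fall back to a
  worse match silently.
- Evidence-class assignment trusts the supplied literature-hit counts; no
  text mining is performed.
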