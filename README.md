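# olfscreen

Analysis pipeline for bulk-RNAseq studies of the olfactory epithelium (OE):
a tissue-overexpression screen with respiratory-contamination filtering and
cross-species rescue, olfactory-receptor (OR) repertoire expression
statistics, a matched-distribution resampling test for inter-individual OR
variability, transcript-model curation with aberrant-splice
pseudogenization detection, and TSS-anchored promoter motif profiling.
Everything runs on a synthetic study generator with planted ground truth,
so every stage's precision and recall is exactly measurable.

It is written for computational biologists who want the statistical
machinery of this study design as tested, reusable code: the screen's exact
count test, the repertoire skew statistics, and the matched-resampling null
are the parts that are easy to get subtly wrong.

## The statistics at the core

**Overexpression screen.** Counts are normalized with median-of-ratios size
factors s_j; per-gene NB dispersion α comes from a within-group
method-of-moments estimate, α = max(0, (Var(q) − q̄)/q̄²) on normalized
counts, floored at the across-gene median. Significance is the exact
conditional NB test: given the total K = K_A + K_B, sum the probabilities
of all splits no more likely than the observed one, with
K_A ~ NB(q₀S_A, α/n_A). A gene is overexpressed when fold ≥ 6 and
p < 0.001 (or rescued by a significant mouse ortholog at human fold > 6),
then removed if FPKM_respiratory / FPKM_OE > 0.1.

**Repertoire skew.** Genes are ranked by mean FPKM; the half-fraction is
the smallest k/n whose top-k genes hold ≥ 50% of the summed expression — a
Lorenz-curve summary of how few receptors dominate the repertoire.

**Inter-individual variability.** For an OE sample pair, the Pearson
correlation of log₁₀ FPKM over the OR set is located in a null of 10,000
control gene sets matched on expression (two-sample KS p > 0.05 against
the OR distribution), with one-sided add-one empirical p
(1 + #{r_null ≤ r_obs})/(N + 1).

See `docs/methods.md` for the full model descriptions, parameter defaults
and limitations.

## Worked example

The numbered scripts under `analysis/` run each stage on the default
synthetic study (6,000 genes, 391 intact + 466 pseudogene OR loci, 4 OE
samples, 1 respiratory, 16 control tissues, fold-8 planted overexpression)
and write tables under `results/`:

```sh
python analysis/03_overexpression_screen.py --seed 0
```

```
non-OR genes screened:        5143
  retained               50
  rescued_by_mouse       0
  respiratory_filtered   12
  failed_fold            5071
  failed_p               10
evidence classes among retained: A=3, B=42
recall of planted overexpressed genes:  0.90
precision of the retained set:          0.90
planted contaminants filtered: 9/10
```

Fifty genes pass the fold ≥ 6 & p < 0.001 rule, recovering 90% of the 50
planted fold-8 genes at 90% precision; 9 of the 10 planted
respiratory-epithelium contaminants are caught by the 0.1 respiratory
ratio filter (the tenth missed the retention rule outright).

```sh
python analysis/04_or_repertoire.py --seed 0
python analysis/05_interindividual_variability.py --seed 0
```

```
human:
  expressed intact/pseudo:   82.6% / 44.6%
  mean FPKM intact/pseudo:   0.29 / 0.04  (KS p = 2.09e-31)
  half-fraction (skew):      2.1%
mouse:
  expressed intact/pseudo:   94.4% / 67.0%
  mean FPKM intact/pseudo:   0.88 / 0.07  (KS p = 2.37e-113)
  half-fraction (skew):      8.6%
...
OE1 vs OE2: OR r = 0.429, matched-null mean r = 0.852, p <9.999e-05 (203 OR genes)
OE1 vs OE3: OR r = 0.313, matched-null mean r = 0.845, p <9.999e-05 (203 OR genes)
```

Intact ORs are expressed far more often and ~4–7× higher than pseudogenes;
a few percent of human ORs carry half the repertoire's expression (the
mouse curve is flatter); and the OR set's between-individual correlation
(~0.3–0.4) lies entirely below the matched-control null (~0.85), so OR
expression is significantly more variable between individuals than
expression-matched genes.

`analysis/06_transcript_structure.py` curates simulated OR transcript
models (940 bp ORF in a long last exon, short 5' non-coding exons) and
recovers every planted ORF-skipping aberrant isoform;
`analysis/07_promoter_motifs.py` recovers the planted 100–300 bp upstream
motif cluster as the modal bin of the 4 kb TSS-anchored profile with
Fisher enrichment p ≈ 1e-11 against background promoters.

A thin CLI wraps the same pipeline: `olfscreen run --seed 0 --out results`.

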