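# Methods

This note records the conventions, models and numerical choices behind
`cerna_scan`, the reasoning where the design was genuinely open, and what
the synthetic benchmarks do and do not show about real data.

## Coordinates and annotation

All internal coordinates are 0-based half-open; GTF I/O converts from the
1-based inclusive file convention at the parse/write boundary. A transcript
is a locus plus sorted, non-overlapping exons on one chromosome and strand;
introns are the gaps between consecutive exons. The GTF reader accepts
`transcript` and `exon` features, takes `biotype` from the attribute column
(defaulting to `coding` when absent), and reports malformed input —
unknown strand, exon crossing its transcript — with file and line number.
BED6 export is provided for browser viewing only.

## Positional classification

The gap between two loci is the end-to-start distance of half-open
intervals: abutting loci have gap 0 and are *not* overlapping. The classes:

* **sense/antisense exon overlap** — ≥1 bp of exon–exon overlap; strand
  equality picks sense vs antisense.
* **sense/antisense intron overlap** — loci overlap without any exon–exon
  overlap.
* **bidirectional** — disjoint loci on opposite strands, oriented head to
  head (both 5′ ends face the inter-locus gap, i.e. divergent
  transcription), gap between 1 and 1000 bp inclusive. Gap 0 (abutting)
  does not qualify; gap 1001 does not qualify.
* **intergenic** — the nearest coding transcript on the lncRNA's chromosome
  is strictly farther than 30 000 bp, or absent. A lncRNA with a coding
  neighbour within 30 kb but no qualifying relation is **unclassified**.

When several relations hold, the reported class follows the precedence
sense_exon > sense_intron > antisense_exon > antisense_intron >
bidirectional > unclassified > intergenic; ties within a class break by
smallest gap, then lexicographic gene name, and all co-qualifying genes of
the winning class are reported in a secondary column. The classifier is
assembly-agnostic.

Two symmetry caveats discovered while testing: flipping *every* strand in an
annotation preserves relative orientation (sense stays sense); the
sense↔antisense swap law holds under flipping the lncRNA strand alone, and
the head-to-head definition is not symmetric under either flip. The
property tests state the laws in that form.

## Homology ("mimicked gene") search

Candidate mimicked genes are found by optimal Smith–Waterman local
alignment (Biopython's PairwiseAligner) with match +1, mismatch −1, gap
open −2, extend −1 (a gap of length k costs 2 + (k−1)); the subject is also
aligned as its reverse complement and the better strand kept. N scores as a
mismatch against everything, including N, and never counts as a match.

Percent identity = matches / alignment columns, gap columns included in the
denominator — Smith–Waterman trims poorly matching ends, so the estimate of
a planted identity is unbiased to slightly high (mean error ≈ 0.1
percentage points, worst case ≈ 2 points at 85 % identity over 400 nt).

A pair **passes** when identity ≥ `min_identity` (default 0.90), the two
loci lie on different chromosomes, and the alignment covers ≥ 50 % of the
shorter sequence. The coverage guard is this package's own addition: local
alignment of two unrelated desk-scale sequences always contains a short
perfect segment (identity 1.0 over ~15 columns), so an identity threshold
alone would pass arbitrary pairs. Coverage is reported per pair; the full
audit table includes failing pairs down to a reporting floor.

When the optimal alignment is not unique, the deterministic traceback may
choose alignments with different column counts for (a,b) vs (b,a); the
score is exactly symmetric, percent identity only for unambiguous optima.
The pipeline always aligns lncRNA → coding in one direction.

## Seed-site scanning

Sites are anchored at the target position opposite miRNA position 1
(miRNA position p faces target index anchor − p + 1). Target motifs are the
reverse complements of the paired miRNA positions, with the A1 adenosine
appended where the type requires one; the A is required in the *target*
regardless of the identity of miRNA position 1. The anchor may reach
len(target) for types that do not read a base there and len(target)+1 for
an offset-6mer at the extreme 3′ end (miRNA positions 1–2 dangle).

Each anchor is reported at most once, labelled with the best-rank type
matching there, so an 8mer is never additionally counted as the 7mer/6mer
types it contains; the same miRNA at distinct anchors counts each time,
overlapping or not. Scanning is sense-strand only (miRNAs bind the mature
transcript), T/U-insensitive, and N matches nothing.

**Imperfect sites** (off by default) are windows opposite miRNA positions
2–7 with exactly one defect: one G:U wobble, one mismatch, or one
single-base deletion of the target window ("missing" operationalized as a
deletion, giving a 5-nt window); they are only reported at anchors without
a perfect type. An unbounded defect count would match almost everywhere,
hence exactly one.

Conservation is a no-op by design: all sites are treated as non-conserved,
and no phylogenetic input is accepted. Vendor aggregate scores
(context/context+, structure, free energy) are not computed; report sorting
uses the site-type hierarchy, then site count, then miRNA id. Pairing of
miRNA positions 13–16 is annotated per site (`supplementary_pairing`) but
never influences calling.

## Expression statistics

* **Quantile normalization**: every column's sorted values are replaced by
  the row means of the column-sorted matrix, in original rank order; tied
  values receive the mean of the quantile values their ranks span. This is
  exactly idempotent up to float summation error (≤1e−12 at log-intensity
  magnitudes).
* **Fold-change filter**: fold = model/normal ratio of linear-scale group
  means of normalized intensities (a `log_means` switch uses geometric
  means instead, recording the mean-of-logs vs log-of-means ambiguity); a
  probe passes when max(fc, 1/fc) ≥ threshold, boundary inclusive, default
  threshold 2.0. A zero normal-group mean is an error, not an infinite
  ratio. P-values accompany the calls: paired t-test with samples paired by
  within-group order when group sizes are equal (the emulated design pairs
  animal i of each group), Welch's t otherwise. No multiple-testing
  correction by default, matching the raw p < 0.05 workflow;
  Benjamini–Hochberg is available behind a flag.
* **ΔΔCt**: per sample ΔCt = Ct_target − Ct_reference; ΔΔCt = mean
  ΔCt(model) − mean ΔCt(normal); relative quantity 2^(−ΔΔCt) with
  amplification efficiency assumed exactly 2. Per-sample 2^(−ΔCt) values
  are retained for t-tests. Reference genes follow assay convention:
  β-actin for lncRNA/mRNA, U6 for miRNA.
* **Pearson correlation** with the two-sided t-transform p (n−2 df);
  zero-variance input is an error at the API level. **Paired t-test** on
  differences with n−1 df; identical vectors give (t=0, p=1) and constant
  non-zero differences give an infinite t with the smallest representable p.

## Triplet nomination

A candidate (lncRNA, mRNA) pair comes from the homology route (passing
mimic pairs) or an explicit pair list; both are first-class. The verdict is
the conjunction described in the README; notes on the open choices:

* Correlations are computed on log2 intensities across **all samples
  pooled** (per-group correlation is available behind a flag). Pooled
  correlation deliberately includes the group-shift component — that is the
  co-expression pattern the design asks about.
* A probe pinned to one rank by quantile normalization has zero variance;
  its correlation is undefined and the clause simply fails (recorded in the
  rejection reasons) rather than aborting the run.
* "Same direction" accepts both-up (the canonical case) and both-down,
  flagged via the reported direction.
* One qualifying shared miRNA suffices; all shared miRNAs are reported with
  their per-clause status.
* No minimum |r| is imposed beyond significance at `alpha` (default 0.05);
  |r| is reported.

The pipeline writes positional, mimic, site, DE and triplet tables plus a
JSON manifest (config with path basenames, seed, rule-set and package
versions). Identical config + seed reproduce every output byte for byte;
floats are written at %.10g.

## Synthetic data

The generator emulates the study design the pipeline targets: two groups of
10 animals (normal vs disease model), lncRNAs planted in each of the six
positional classes (placement re-verified against the classifier, with an
explicit infeasibility error after 100 attempts), homolog pairs at planted
identities 85/90/93/100 % created by substituting exactly
round((1−identity)·length) positions of a 400-nt sequence, 10 random
22-nt miRNAs, one planted ceRNA triplet (lncRNA up 2.5×, homologous mRNA up
2.2× with target r = +0.9, shared-seed miRNA down to 0.4× with target
r = −0.85 — the validated co-expression pattern), and Ct tables whose
noiseless 2^(−ΔΔCt) equals the planted fold.

Intensities are log2-normal: value = 2^(base + log2(fold)·1[model] +
noise_sd·g) with noise_sd = 0.1 log2 units, so planted folds hold exactly
on the linear scale in the noiseless limit. Correlated triplets share a
per-sample latent factor with loadings √r_pos, √r_pos and −|r_neg|/√r_pos,
giving expected log-scale correlations (+r_pos, −|r_neg|); feasibility
requires |r_neg| ≤ √r_pos. Baselines are Gaussian (log2 N(9, 1.5)) over
1000 background probes; planted probes draw central baselines (N(9, 0.5))
because quantile normalization provably compresses fold changes at the rank
extremes — a bounded or edge-placed baseline makes planted truth
unrecoverable for reasons unrelated to the statistics under test. Planted
seed sites are written into scrubbed backgrounds (no accidental perfect
site for any simulated miRNA), with one-base guard flanks so a planted
7mer-m8 is not accidentally upgraded to an 8mer, and re-scanned
immediately; homolog-pair substitutions avoid planted-site spans so shared
MREs survive on both sides.

One integer seed drives fixed-stage derived streams; identical configs give
byte-identical output bundles.

**What the generator does not emulate**: probe-level hybridization physics,
background correction, batch effects, heavy-tailed or heteroscedastic
noise, correlated null genes, genome-scale annotation density, repeat
sequence, or real miRNA families. Passing the planted-truth benchmarks
shows the algorithms implement their definitions and recover signal under
the stated noise model at desk scale; it does not certify performance on
real microarray or sequencing data.

## Problem sizes and determinism in the benchmarks

The test suite checks oracle equivalence of the scanner on 10⁴ random
(target, miRNA) cases (targets to 1 kb) and of the classifier on 10⁴ random
annotations plus explicit 1000/1001 bp and 30 000/30 001 bp boundary
geometries; t-test calibration uses 10⁴ null replicates; the null
nomination rate uses 200 expression seeds over the fixed default structure.
`scripts/acceptance.py` re-derives all inputs from its `--seed` and uses
2000 planted-site cases, 150 annotation seeds, 100 homolog pairs, 300
correlation seeds and the same 200-seed null, finishing in well under a
minute on one CPU. All randomness in tests and script flows through
explicitly seeded NumPy generators.

## Known limitations

* No genome-scale alignment seeding (the all-vs-all Smith–Waterman is meant
  for dozens of transcripts, not transcriptomes), no E-values, no
  protein-level alignment.
* No thermodynamic duplex folding or context-feature scoring for sites;
  ranking is by site-type hierarchy and count only.
* ΔΔCt assumes perfect amplification efficiency; no dilution-curve
  estimation.
* Nomination is correlational; it claims a candidate sponge pattern, not a
  mechanism — experimental validation is out of scope by design.
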