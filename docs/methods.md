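# Methods

## Locus model and feature space

The α-globin cluster is modelled as a set of half-open intervals on GRCh38
chr16 (0-based, BED convention).  The default analysis region is 21 kb,
chr16:160,000–181,000, tiled by 66 contiguous bins (~318 bp each; widths
differ by at most 1 bp and sum exactly to the region length).  Default
deletion intervals approximate the published extents:

| allele | interval (chr16) | functional α genes |
|---|---|---|
| αα (normal) | — | 2 |
| −α3.7 | 173,700–177,400 | 1 |
| −α4.2 | 168,700–172,900 | 1 |
| −−SEA | 165,400–184,700 | 0 |
| −−THAI | 162,000–196,500 | 0 |
| −−FIL | 156,000–189,000 | 0 |

Exact breakpoints vary by assay and are not constants of the method: all
geometry is configuration (YAML / BED), and every computed result depends
only on the configured intervals.

A genotype's **copy-fraction track** assigns each bin the length-weighted
mean of (intact haplotypes at that position)/2 — 1.0 for diploid, 0.5 under
a heterozygous deletion, 0.0 where both haplotypes are deleted.  It is
symmetric in the two haplotypes and bounded in [0, 1].

One deliberate geometric choice: the region's left margin extends past the
THAI breakpoint.  The features are within-sample TPM values, which are
scale-free; a deletion covering *every* bin shifts all counts by the same
factor and is therefore invisible after normalization.  Detectability
requires bins outside the deletion.  With the default geometry −−THAI leaves
~6 intact bins and is detectable; −−FIL covers the whole region and a
heterozygous FIL carrier is *not* distinguishable from normal by these
features (FIL has default population frequency 0 here and did not occur in
the motivating cohort; widening the region restores the signal).

## Counting and normalization

A fragment is a properly paired read pair's outer span.  Each fragment
overlapping at least one bin increments exactly one bin — largest overlap,
ties to the leftmost — emulating unique feature assignment; this conserves
the total count across adjacent bins.  Counting is vectorised but tested
against an exhaustive per-fragment overlap scan on random instances.

Raw counts are normalized TPM-style: per-bin rate `raw_i·10³/length_i`,
rescaled to sum to 10⁶.  The published formula for this normalization is
printed in a self-cancelling form; it is implemented here in the standard
form (length correction then library-size rescaling), which is the only
reading that "accounts for feature length and sequencing depth".  Every
profile's TPM vector sums to 10⁶ (relative tolerance 10⁻⁶); an all-zero
count vector is an error, never silently normalized.

## Synthetic cfDNA generator

Per sample with genotype copy fractions `c_i`:

* bias `b_i ~ LogNormal(−σ²/2, σ)` drawn once per sample per bin (unit
  mean); default σ = 0.1.  This stands in for capture-efficiency,
  GC and mappability bias, including HBA1/HBA2 homology effects.
* expected depth `μ_i = D · (L_i/ΣL) · c_i · b_i` with D the expected
  fragment count over the region.  Default D ≈ 234,289 fragments,
  converted from the study's ~1852X mean target coverage over 21 kb with
  166 bp fragments (`coverage_to_fragments`).
* raw counts `~ NegBin(μ_i, k)` with variance `μ + μ²/k`; default k = 20,
  `k = ∞` gives Poisson.

`simulate_fragments` draws per-bin counts from the same model and places
fragment midpoints uniformly within each bin (lengths Normal(166, 40) bp
truncated to [50, 500]), so the fragment route and the count route are
statistically consistent by construction.

An optional fetal admixture mixes the maternal track with a fetal one
(`(1−f)·maternal + f·fetal`), the fetal genotype inheriting one maternal
haplotype uniformly and a paternal haplotype from population allele
frequencies.  Default f = 0: the classifier targets the maternal genotype
and treats fetal signal as noise.

**What the simulator does not capture**: read-level errors, mismapping
between the homologous α genes, GC waves correlated across samples,
breakpoint micro-heterogeneity, and real cfDNA fragmentation patterns.
Passing synthetic-recovery tests therefore demonstrates the pipeline's
correctness and statistical power under this noise model, not clinical
performance on real cohorts.

## Two-stage ensemble

Features are the 66 TPM values.  The cohort is split stratified by the five
class labels (default 60:20:20 train/validate/test), so validation and test
sets keep population prevalence; any class with fewer than 3 samples is an
error.  Stage 1 (normal vs abnormal) trains on a rebalanced set: the normal
majority is down-sampled without replacement to the abnormal count.  Stage 2
(αα/−−SEA, αα/−α3.7, αα/−α4.2, Others) trains on the truth-labelled abnormal
subset of the *un-rebalanced* training data — not on stage-1 positives — to
avoid leaking stage-1 errors into stage-2 labels.  Stage-2 class imbalance is
left as-is.  At prediction, stage-1 P(abnormal) ≤ 0.5 ⇒ aa_aa, final; else
the stage-2 argmax.  The validation split is used only for logged macro-F1;
the test split is never touched in training.

Random forests use 500 trees, √p features per split, minimum leaf 1, no
depth cap (standard defaults; the source description specifies none), all
seeded and single-threaded for bit-reproducible fits.  Models persist via
joblib with an explicit format version, the feature schema (bin count +
normalization flag) and training metadata; loading a mismatched version is
an error, and a round trip reproduces predictions bit-exactly.

Benchmark sizes were chosen to exercise the method at desk scale: the
acceptance benchmark simulates 7,000 samples at the study genotype mix
(5,000 train / 1,000 validate / 1,000 test) and requires stage-1 abnormal
sensitivity ≥ 0.99 and macro-F1 ≥ 0.95 over the four common classes; unit
tests use cohorts of a few hundred to a few thousand samples.

## Population burden under Hardy–Weinberg

Each individual in a genotype-count table contributes two haplotypes;
allele frequencies are haplotype counts over 2N.  Alleles pool into three
functional classes — p_norm (αα), p_plus (−α3.7 + −α4.2), p_zero (−−SEA +
−−THAI + −−FIL) — because phenotype depends only on the functional α-gene
count (4 → normal, 3 → silent carrier, 2 → trait, 1 → Hb H, 0 → Hb Bart's).
Pooling −−THAI with −−SEA as α0 is what makes the class algebra close; the
Punnett expansion (p_norm + p_plus + p_zero)² then yields the five phenotype
frequencies, which sum to 1 identically.  Birth projections round
half-away-from-zero to whole newborns and also report the sum over Hb H +
trait + silent carrier — the births a screening programme would flag.  (The
motivating report quotes both 106,686 and a figure matching the computed sum
106,681 for this total; the package reports the computed sum.)

No inbreeding or population-structure correction is applied and no
confidence intervals are attached to the HWE expectations; both are natural
extensions.

## Numerical and design notes

* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical config + seed ⇒ bit-identical
  simulations, splits, fits and predictions.
* Counting ties (equal overlap with two bins) resolve to the leftmost bin —
  deterministic and order-independent.
* Stratified splitting rounds per-class validate/test sizes to the nearest
  sample (minimum 1), so split proportions are exact to within one sample
  per class.
* Undefined metric ratios (0/0, e.g. specificity with single-class truth)
  are reported as NaN, never coerced to 0.
* Metric percentages are formatted to 2 decimals in reports; full precision
  is kept internally.
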