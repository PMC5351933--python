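# Methods

This note records the models, conventions and design choices behind
`haplofoot`, in the spirit of a statistical software appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinates and interval semantics

All internal coordinates are 0-based half-open (BED convention). Variant
positions read from the VCF-like panel format (1-based) become single-base
intervals `[pos−1, pos)` on input. Overlap means ≥ 1 shared base; touching
intervals do not overlap. Strand is stored but ignored by every interval
operation. Interval queries run on per-chromosome sorted/merged numpy
arrays (binary search), which also back the dense coverage masks the
permutation machinery uses; this assumes chromosomes small enough to hold a
per-base array in memory, which holds for the megabase-scale synthetic
genomes this package targets (real whole-genome masks at 3 Gb would need
~3 GB per annotation and would warrant a sparse rewrite).

## LD and haplotype blocks

r² is computed exactly from phased haplotype columns (allele-frequency
formula; no EM from unphased genotypes). Monomorphic variants have
*undefined* LD and are excluded from blocks rather than scored 0 — the
behaviour of standard LD tools, which emit no record for such pairs. The
block of a sentinel is the sentinel (at r² = 1) plus all same-chromosome
variants within a window (default 10 Mb) at r² ≥ threshold; the boundary is
inclusive. Sentinels sharing linked SNVs stay separate blocks, and
duplicated sentinel ids yield duplicated blocks: Π denominators are per
reported association. The Π grid evaluation computes, per sentinel and
annotation layer, the maximum r² over annotation-flagged variants in the
window (one matrix product per chromosome chunk); a block hits at threshold
t iff that maximum ≥ t, which is algebraically identical to expanding
blocks per threshold (the test suite cross-checks this equivalence).

## Footprint QC

Filters run in a fixed order: blacklist (≥ 1 bp overlap removes), autosome
restriction, width bounds (default 11–22 bp), artefact filter, then —
because centiles depend on the surviving set — the score-centile threshold
last. The artefact filter targets single-position PCR/alignment spikes:
with the footprint centre defined as `start + floor(length/2)`, a footprint
is removed when one position contributes more than 50% of the total cut
signal within ±100 bp of the centre. The phrase "skew by > 50%" admits a
second reading — left/right half-window imbalance — which ships behind
`mode="leftright"` without any claim about which reading upstream tools
used; the spike reading is the default because it is the artefact class
such filters exist for. All-zero windows are kept with ratio 0.

## Score calibration

TF classes come from an RPKM table: highly expressed (RPKM > 10 in every
sample), undetectable (RPKM = 0 in every sample), expressed (≥ 1 in ≥ 1
sample). The TP proxy couples expression with conservation: an
expressed-TF motif counts only if its mean track value exceeds the mean
over its two abutting 50-bp flanks by > 0.1 (per occurrence, not averaged
per TF); the undetectable side is deliberately ungated, mirroring the
asymmetric proxy definition. "Scaled for the size of motif tracks" is read
as per-bp density: (fraction of footprints overlapping the class) / (bp of
the class's motif track) — the only scale-free normalisation that makes the
two classes comparable. The chosen threshold is the smallest grid centile
(default grid 0, 5, …, 95) whose ratio reaches the target (default 2.0); a
zero-denominator overlap yields an infinite-ratio sentinel, and an
unreachable target returns no threshold together with the full curve.

## Motif scanning and disruption

Scoring is log₂ odds of the position probability matrix (optional
pseudocount mixed toward the background) against a 0-order background,
discretised to 1e-3 log-odds bins. The background score distribution is
computed by exact convolution over positions; the threshold for tail
probability p follows FIMO semantics: the smallest *achievable* score whose
tail is ≤ p, falling back to the maximal score (with a warning) when p is
below the minimal achievable tail. A 0-order background was chosen over a
1st-order Markov model to keep the p-values exactly enumerable; 1st-order
scanning is out of scope. Scanning covers both strands; windows containing
N or masked (lowercase) bases are skipped; ties at the threshold count as
hits. A variant is disruptive when substituting the alternate base flips
match status at the p threshold in either direction — gains count as well
as losses, since a created site is as biologically meaningful as a
destroyed one.

The disruption test statistic is the fraction of footprint-contained SNVs
disruptive to ≥ 1 overlapping motif hit. The null re-places every footprint
uniformly within a uniformly chosen DHS large enough to contain it (DHS
choice is uniform over capable DHS, not length-weighted — each shuffle
preserves footprint lengths and containment); shuffles that trap no SNV
contribute a proportion of 0, and p = (#{null ≥ observed} + 1)/(n + 1).

## Enrichment

The default statistic is the count of query segments overlapping ≥ 1
annotation bp (a bp mode exists); segment counting was preferred because Π
and haplotype hits are segment-level calls. Null placement picks a
workspace segment with probability proportional to its number of valid
placements (length − item length + 1) among segments that can contain the
item, then a uniform offset — i.e. uniform over all valid placements.
Empirical p-values use the add-one estimator (never 0); two-sided doubles
the smaller tail. GC-isochore correction generalises to arbitrary strata
labels on workspace segments (the synthetic genome has no sequence); a
helper assigns quintile strata from a per-segment value, and a constant
label reproduces the unstratified run exactly because the unstratified
path is the single-stratum special case. BH correction is delegated to
statsmodels.

## The synthetic-data generator

Defaults define the study conditions: 2 chromosomes × 1 Mb, 1,200
non-overlapping DHS (200–400 bp, ≥ 250 bp apart, ≥ 300 bp from chromosome
ends), footprint probability 0.8 per DHS (one footprint, 11–22 bp, fully
inside), 20,000 panel SNVs over 380 haplotypes in 10 kb LD blocks at target
within-block r² = 0.8, 10,000 sentinels with a planted 1.65-fold footprint
enrichment, 16 TF motifs of length 8 (half expressed, half undetectable),
conservation signal +0.5, artefact probability 0.05 per footprint. The
planted fold mirrors the magnitude of enrichment reported for tissue-matched
regulatory variants in footprints; sample sizes were chosen once so that
every planted effect is recoverable with comfortable error bands on one
CPU in seconds.

Mechanisms, and what they do and do not emulate:

* **LD** uses an ancestral-column copy scheme: each variant in a block is
  the block's Bernoulli(½) ancestral column with independent per-haplotype
  flips at rate ε = (1 − r²^{1/4})/2, giving pairwise r² = (1−2ε)⁴ =
  the target in expectation. This produces flat within-block LD and no
  between-block LD — not coalescent-accurate distance decay.
* **Planted sentinel enrichment**: each sentinel falls inside a footprint
  with probability `planted_fold × baseline`, where baseline is the
  footprint fraction of DHS base pairs — exactly the overlap rate of the
  within-DHS permutation null, so the permutation fold estimate is an
  unbiased estimator of the planted fold. (An earlier variant-count
  baseline made the estimate noisy-biased through the finite number of
  footprint variants.) In-footprint sentinels are drawn uniformly from
  footprint variants, others from DHS-not-footprint variants; the truth
  record stores the causal indices and realized fold.
* **Artefacts**: cut counts are Poisson(5) over DHS; artefact footprints
  get one position within ±100 bp of the centre set to 10× the remaining
  window total, so its share is ~10/11 of the window and the > 50% filter
  fires on exactly the planted set, while clean footprints (max/total
  ≈ 0.03) never trigger it. A literal "multiply one position by 10" would
  leave the spike far below 50% of a ±100 bp Poisson window and make the
  planted labels unrecoverable, so dominance over the window total is the
  planted definition.
* **Calibration geometry**: footprints in the top 40% of scores
  ("high-quality") each carry one expressed-TF motif; the rest each carry
  one undetectable-TF motif (one motif per footprint — this also keeps
  motif occurrences disjoint so planted ref alleles are unambiguous).
  Conservation noise is N(0, 0.3) over DHS ± 150 bp, with the signal added
  only over expressed-TF occurrences. With per-bp density normalisation the
  expected TP:FP ratio at centile c equals n_LQ / (kept LQ footprints),
  crossing 2.0 when half the low-quality footprints are filtered — at the
  ~30th centile under the defaults. The truth record stores that analytic
  crossing (`expected_chosen_centile`); it, not the 60th-centile quality
  boundary itself, is what the calibration estimates.
* **Disruption**: every PWM has a dominant base (0.85) per position, so the
  consensus k-mer passes p ≤ 10⁻⁴ at length 8 while any single mismatch
  fails; SNVs inside motif occurrences get the consensus base as ref and a
  minimal-probability base as alt, making them disruptive by construction
  (ids in the truth record). Motif length must be ≥ 7 for the consensus to
  clear 10⁻⁴ under a uniform background (0.25⁷ ≈ 6e-5); the default is 8.
* **Tracks** are defined (non-zero) only over DHS neighbourhoods; the
  on-disk format stores non-zero positions and reads missing positions
  as 0. Floats are written via `repr` (shortest round-trip form) and read
  with round-trip parsing, so write→read is bit-exact.

Passing tests on these data show the *statistical machinery* is correct and
calibrated; they cannot show robustness to features real data add —
LD decay, overlapping footprints, non-uniform variant density, sequence
composition bias, real footprint score distributions.

## Determinism and problem sizes

Every generator and test threads a single integer seed through
`numpy.random.default_rng` / `SeedSequence`; the same seed reproduces
datasets (manifest checksums) and pipeline reports byte-for-byte. The test
suite runs enrichment at 2,000 randomisations, the type-I calibration at
200 null replicates × 499 randomisations, and the disruption test at 1,000
shuffles — sizes chosen as the package's own balance between statistical
resolution and a suite that completes in a few minutes; the pipeline
default remains 10,000 randomisations.

## Known limitations

* No real-data ingestion beyond the simple text formats (BED, VCF-like
  panel, per-base TSV tracks, MEME minimal, long-format RPKM).
* Segment-vs-bp counting in the enrichment statistic is a user choice; the
  two can disagree for long queries.
* The Δlog-conservation gate is per occurrence; a per-TF averaged gate is a
  plausible alternative left to sensitivity analysis.
* Whether footprint and motif must mutually overlap at the SNV (rather
  than each merely contain it) is resolved by using the
  footprint∩motif intersection intervals as the layer.
* Indels, multi-allelic sites, D′, imputation and fine-mapping are out of
  scope.
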