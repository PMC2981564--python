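# Methods

## Data model and conventions

All genomic coordinates are 1-based inclusive internally; BED input
(0-based half-open) is converted at the I/O boundary, and the conversion
is an involution. Region length is `end − start + 1`. Only autosomes
(chromosomes 1–22) are analysed; non-autosomal records are skipped with a
logged warning rather than an error, since sex chromosomes need a
different diploid baseline. A missing call rate in a manifest is treated
as 1.0 with a warning so that synthetic manifests can omit it.

## Sample QC

Samples whose genome-wide array call rate is strictly below
`min_call_rate` (default 0.98) are discarded; a call rate exactly at the
threshold is retained, because the rule excludes samples *below* the
minimum. Array-image-level QC (hybridisation contrast) happens upstream of
this pipeline's inputs and is out of scope.

## Low-confidence segment merging

Callers tile each chromosome wall-to-wall with integer-CN segments; many
are short, low-confidence fragments. Segments with confidence strictly
below `confidence_threshold` (default 5; the boundary value counts as
confident) are absorbed into a confident neighbour, adopting its copy
number and confidence. "Adjacent" is ambiguous when confident neighbours
exist on both sides; we resolve it **per segment** to the neighbour with
the smaller genomic gap in base pairs (spans of intervening segments count
toward the distance), with ties going upstream (lower coordinate). This
per-segment nearest-neighbour rule is deterministic, locality-preserving,
and exactly reproducible by brute-force enumeration, which the test suite
exploits as an oracle; a run of consecutive low-confidence segments is
therefore *usually* absorbed as a block but may split when its two ends
are genuinely closer to different confident donors. An absorbed segment
contiguous with its donor extends the donor's interval; otherwise it keeps
its own interval with the donor's copy number, so the union of covered
base pairs per chromosome is never changed by merging. A chromosome with
no confident segment at all has nothing to merge into; its segments are
dropped with a warning. After one pass every segment is confident, so the
merge is trivially at fixpoint.

Variant extraction then keeps exactly the confident, non-diploid
(CN ≠ 2), autosomal segments. Raising the confidence threshold can never
increase the number of extracted variants (tested as a property).

## Cataloguing and novel-CNVR clustering

Each variant call is assigned to the reference CNP region it overlaps
most. The overlap rule — any ≥ 1 bp overlap qualifies, largest overlap in
bp wins, exact ties go to the lexicographically lower region id — is a
package choice; interval queries use an interval tree. Calls overlapping
no library region are *novel* and are clustered per chromosome by single
linkage: calls whose spans overlap or whose gap is at most
`max_novel_gap` (default 1 Mb) join one cluster, which becomes a CNVR
spanning its members' outermost breakpoints. The 1 Mb default reflects
the distance over which a single variant can still perturb the regulation
and expression of nearby genes; it is configurable because smaller gaps
are also defensible. Clustering is equivalent to connected components of
the overlap-or-near graph (the tests verify this against networkx).

A region's variant class is *deletion* if every member call has CN < 2,
*amplification* if every member has CN > 2, and *both* otherwise. The
final report keeps regions strictly longer than `min_region_length`
(default 1,000 bp) containing at least `min_probes` (default 3) array
probe positions; "consecutive probes" is implemented as an in-span probe
count, since probes within one region of a position-sorted map are
consecutive by construction.

## Association statistics

A subject has a region's CNV iff any of their confident variant calls
overlaps it by ≥ 1 bp (duplicate calls count once). On the resulting
boolean presence matrix:

- **Enrichment.** A region is enriched in a case cohort when
  `f_case > 0.40` (strict) and `f_case ≥ 1.5 · f_ctrl`; depleted is the
  mirror image; otherwise neither. The fold comparison is ≥, not strict:
  a fold of exactly 1.5 qualifies, while 1.48 does not. A zero control
  frequency with a qualifying case frequency is enriched. The rule is
  antisymmetric under swapping the cohorts (property-tested).
- **Per-region significance.** Pearson χ² with Yates continuity
  correction, 1 df, two-sided, on the 2×2 present/absent × cohort table
  (scipy's implementation, which clamps the correction so the statistic
  stays ≥ 0). The choice of the corrected statistic is verified in the
  tests against an independent closed form
  (`p = erfc(√(χ²/2))` with the Yates statistic computed from the
  definition). A table with a zero row or column margin has no variance
  to test and yields p = 1.0 with a warning. No multiple-testing
  correction is applied across regions.
- **Cross-cohort overlap and its permutation null.** The observed
  statistic is the number of regions enriched in *both* disease cohorts
  relative to controls. Keeping the three group sizes fixed, group labels
  are reshuffled uniformly at random (twins permuted as individuals,
  matching label-level reshuffling; pair-preserving permutation can be
  composed from the same primitives), the count is recomputed per
  permutation, and `p = #(null ≥ observed) / N` with no +1 smoothing, so
  p-values lie exactly on the grid {0, 1/N, …, 1}. Default N = 1,000.
  With a fixed seed the full null vector is bit-reproducible. The region
  universe (library + discovered CNVRs) is frozen before permuting;
  re-discovering novel regions per permutation would confound the null
  with discovery variance.
- **Twin discordance.** For each region, the count of pairs where only
  the affected twin carries the variant and the count where only the
  unaffected twin does; concordant pairs contribute to neither.

For cross-disease comparison the unrelated cases are pooled with both
members of every twin pair (a manifest-level grouping, not hard-coded),
and each pooled cohort is compared to controls with the same χ², flagged
at the p < 0.05 / 0.005 / 0.0005 tiers.

## ΔΔCt qPCR copy-number calling

With amplification efficiency assumed exactly 2 per cycle (plain ΔΔCt, no
standard-curve correction): `ΔCt = mean(target Ct) − mean(reference Ct)`,
`ΔΔCt = ΔCt − ΔCt_calibrator`, `CN = 2·2^(−ΔΔCt)`. The calibrator anchors
copy number 2 at the per-assay **median** ΔCt across samples — no
designated reference sample is needed, and the median is robust when a
minority of samples are non-diploid. The integer call rounds half away
from zero and floors at 0. Since the vendor tool's confidence model is
proprietary, we define confidence as the product of a rounding-error
factor `max(0, 1 − 2·|CN − round(CN)|)` (1 on an integer, 0 at a
midpoint) and a replicate-consistency factor `exp(−Var(replicate ΔCt))`
(population variance, so it is defined for duplicates); it is monotone in
both error sources and testable, but its absolute scale is not comparable
to the vendor's. Copy number 0 never amplifies; the generator emits a
sentinel Ct of 40, which the caller correctly maps to ≈ 0 copies.
Percent agreement between array and qPCR integer calls is reported per
array-CN class and overall, over the intersection of keyed calls.

## Synthetic-study generator

The generator emulates the *structure* of array-caller output: explicit
CN2 baseline segments tiling each chromosome (so merging is exercised),
planted non-diploid calls, and low-confidence slivers (1–10 kb, confidence
uniform below the threshold, at most one per chromosome per sample at a
10% fragmentation rate, placed strictly interior to a baseline segment).
Defaults mirror the emulated study design: 19 controls, 18 cases, 10 twin
pairs; a 1,320-region CNP library with log-uniform sizes 1–100 kb placed
disjointly and uniformly; and nine planted differential regions whose
classes and per-cohort frequencies equal the published table values
(five case-enriched deletions, three depleted deletions, one depleted
mixed-class novel CNVR of 1.31 Mb). The default genome model is 22
chromosomes of 50 Mb for speed; real hg18 autosome lengths are available
(`GENOME_HG18`), under which the planted regions sit at their real
coordinates (they are rescaled proportionally on shorter genomes). Novel
planted regions emit partial sub-span calls (10–60% of the region,
uniformly placed) to mimic breakpoint heterogeneity; library CNPs are
called at full span, as predefined-region genotyping does. Probe maps
combine a 5 kb background grid with 5 targeted probes per catalogued
region, mirroring array designs that enrich probes in known CNP regions.

Carrier selection has two modes. `exact` (default) plants
`round_half_up(freq·n)` carriers with random identities, so the realised
cohort frequency equals the target and planted status is recoverable
deterministically — the right conditions for pipeline-recovery tests,
given that two of the planted folds (1.53, 1.55) sit at the 1.5
threshold and would flip under sampling noise. `binomial` draws carriers
independently with probability `freq` and is used for calibration and
sampling-noise studies. Twin pairs draw carriers at the pair level
(co-twins concordant) except at explicitly designated discordant regions,
which are present in exactly one designated co-twin per pair.

What the generator does **not** emulate: probe-level intensities and the
caller's segmentation (segments are planted, not inferred), linkage
structure between regions, background common polymorphism at non-planted
library CNPs (baseline regions are diploid apart from slivers, so the
end-to-end false-flag rate measures pipeline artefacts, not binomial
noise), mosaicism, and batch effects. Passing recovery tests therefore
shows the pipeline machinery is correct under its stated rules, not that
the thresholds are optimal for real arrays.

## Numerical and reproducibility choices

Coordinates are integer arithmetic throughout. All simulation and
permutation randomness flows from `numpy.random.default_rng` seeded
explicitly; identical config + seed gives byte-identical files. Frequency
comparisons use double precision; the 40% threshold is strict and the
1.5-fold threshold inclusive, so table-value inputs (integer percents)
are never on a representability boundary. p-values print as two decimals,
falling back to three (then to scientific notation) when they would
render as 0.00.

## Problem sizes used in the checks

The calibration check runs 200 independent null cohorts (57 samples × 50
regions, presence probability 0.5) at 1,000 permutations each; the
planted-effect check uses 5 regions at 90%/20% frequencies with group
sizes 19/18/20; qPCR recovery uses 500 synthetic measurements (diploid
majority) at Ct noise σ = 0.05; end-to-end recovery runs the full
pipeline on 100 seeded studies in the test suite and 50 in the
acceptance script, at the full default scale (1,320-region library, 57
samples).

## Known limitations

- The merge rule resolves an ambiguity (two-sided adjacency) that real
  upstream pipelines may have resolved differently; both the block and
  per-segment readings agree on single low-confidence fragments, which
  dominate in practice.
- The enrichment rule is a frequency heuristic, not a model; with n ≈ 20
  per cohort its observed folds are noisy, which is precisely why the
  permutation test accompanies it.
- The permutation p has resolution 1/N and is conservative for discrete
  statistics; under the null its distribution is sub-uniform, which the
  calibration test's acceptance band (2–9% at the 5% level) reflects.
- qPCR confidence values are comparable within this package only.
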