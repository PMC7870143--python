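# Methods

`sexsignal` infers the genetic sex-determination (SD) system of a
population — male heterogamety (XX/XY), female heterogamety (ZZ/ZW), or
no detectable genetic signal — from four complementary views of
population genomic data, and ships a synthetic-population generator so
that every inference path can be validated against planted truth. This
note records the models, the parameters that matter, and the design
choices made where more than one reasonable convention exists.

## Carrier association (sexassoc)

When a candidate master sex-determining sequence can be genotyped as
present/absent per individual (e.g. a male-limited *amh* duplicate
assayed by PCR), sex linkage is tested on the 2×2 table of sex ×
carrier status with the Pearson chi-square test with Yates continuity
correction, one degree of freedom:

    χ² = n (max(|ad − bc| − n/2, 0))² / ((a+b)(c+d)(a+c)(b+d))

where `a,b` are carrier/non-carrier males and `c,d` carrier/non-carrier
females. The correction is clamped at zero so the statistic is never
negative. Tables with a zero margin (marker absent from everyone, or a
single-sex sample) carry no association information; they are reported
as degenerate with p = 1 rather than raising a division error, and the
report distinguishes "carrier absent" from "carrier present but
unlinked". Human-readable output floors p-values at the conventional
`<2.2E-16`; machine output keeps the raw float.

The test variant matters: this corrected chi-square reproduces the
p-values printed in published surveys of *amh*-duplicate sex linkage in
esociform fishes at their printed precision (e.g. 0.0114 for 5/5
carrier males vs 0/5 carrier females), which neither the uncorrected
chi-square nor Fisher's exact test does. One published row (Iowa
muskellunge, 18/27 vs 4/18, printed 2.01E-08) is *not* reproduced by
this or any standard 2×2 test we tried (the corrected chi-square gives
≈0.0089); we treat that printed value as unexplained and exclude it
from validation rather than guess at the original calculation.

The test suite cross-checks the chi-square tail against an independent
oracle — direct numerical quadrature of the 1-dof chi-square density —
over every table with n ≤ 12.

## RAD presence/absence markers (radmarkers)

A RAD marker is a distinct exact read sequence; variants are never
merged (non-polymorphic marker convention), so X/Y-differentiated loci
appear as separate markers rather than heterozygous genotypes. A marker
is *present* in an individual when its depth is ≥ `min_depth` (default
10, inclusive). For each tile (m, f) of the (M+1)×(F+1) marker-by-sex
distribution, significance is the Yates chi-square on
((m, M−m), (f, F−f)) compared to a Bonferroni threshold of
α / ((M+1)(F+1)) — the correction denominator is the number of possible
tiles, matching the tile-level display the test accompanies. Raising
`min_depth` can only remove presence calls, so the tile distribution is
monotone in the threshold.

The physical size of a non-recombining sex locus is estimated from the
number of significant markers and the genome's restriction-site
density: single-digest RAD produces one marker on each flank of a cut
site, so

    size (Mb) ≈ n_significant / (2 × sites_per_Mb).

The "small" (< 0.5 Mb) / "large" label attached to this estimate is a
reporting convention, not an inference. Site density is counted on the
forward strand with overlaps allowed; palindromic motifs (such as the
SbfI site CCTGCAGG) therefore count once per genomic position.

## Pooled sequencing scan (poolsig)

Input is a per-site A/C/G/T count table for one male and one female
pool. Defaults follow the standard pooled sex-scan parameterisation:
`freq-het 0.5`, `range-het 0.15`, `freq-hom 1`, `range-hom 0.05`,
`min-depth 1`, window size 50 kb, output resolution 1 kb.

*Sex-specific SNPs.* A site is male-specific when the male pool looks
heterozygous — at least two alleles observed, with some allele at
frequency within `freq_het ± range_het` that differs from the female
pool's major allele — while the female pool is fixed (major-allele
frequency ≥ `freq_hom − range_hom`); and symmetrically for
female-specific sites. This is the minimal explicit rule consistent
with the parameter names and the purpose (detecting alleles private to
one sex's sex-limited chromosome); published pipelines do not spell the
rule out. All frequency comparisons are inclusive, with a 1e-9 slack so
exact rational boundaries (13/20 vs 0.5 + 0.15) compare equal in
floating point. Sites where either pool is below `min_depth` are
skipped as uncovered. Adjacent significant sites are reported
individually; window aggregation provides the grouping (we do not
reimplement the undocumented "group-snps" collapsing of neighbouring
sites).

*FST.* Between-pool differentiation uses the parameter-free
heterozygosity-ratio (Nei) form FST = (H_T − H_S)/H_T, with H_T from
the mean of the two pools' allele frequencies and H_S the mean
within-pool expected heterozygosity, clamped to [0, 1] and defined as 0
when H_T = 0. The estimator is isolated behind `site_fst` and is
swappable. Hand-computable cases (identical pools → 0; fixed difference
→ 1; 0.5/0.5 vs fixed → 1/3) are asserted exactly.

*Windows.* Both tiled (non-overlapping 50 kb, the display convention)
and sliding (50 kb advanced by the 1 kb output resolution, the
computation convention) modes are provided, since published figure
legends and methods sections disagree on which was used; tiled is the
default. Tiled window SNP counts sum exactly to the per-site totals.

*Hemizygous (Y/W-specific) windows.* A sequence present on only one
chromosome copy of the carrier sex is covered at ~half the carrier
pool's depth and ~zero in the other pool. A 1 kb window is flagged when
female coverage is strictly below 3 per kb and male depth relative to
the genome-wide male mean lies inclusively in [0.4, 0.6]; the strict
female cutoff follows the published filter's wording, every other
boundary in the package is inclusive. Because the pipeline input is a
per-site count table with no read structure, "reads per kb" is
implemented as the mean per-site depth over the 1 kb window. The
relative-depth baseline is the genome-wide *mean* male depth over
male-covered sites (not the median), matching "half of the genome
average". Adjacent flagged windows merge into BED regions (0-based,
half-open; all text output positions are otherwise 1-based).

## Sex-biased k-mers (kmersex)

Canonical 31-mers (lexicographic minimum of k-mer and reverse
complement) are counted per pool; windows containing non-ACGT symbols
are skipped entirely. Occurrence filters mirror a read-based k-mer
counter's count stage: keep k-mers with count strictly > 5 and strictly
< 50,000,000, applied per pool before merging. After merging, a k-mer
is sex-biased when it occurs strictly more than 25 times in one sex and
strictly fewer than 5 times in the other. Tables are stored as sorted
64-bit 2-bit-packed codes with parallel count arrays, so genome-scale
tables fit comfortably in memory while still exposing a mapping
interface.

Heterogamety is called from the two sex-specific k-mer counts: ZW when
female-specific k-mers outnumber male-specific ones by ≥ 10× and reach
at least 1,000 (XY symmetric), otherwise undetermined. Published
analyses report such excesses (e.g. a 45× female excess implying ZW)
without stating a decision rule; the 10× / 1,000 convention is this
package's, is configurable, and is printed in every report. With a zero
denominator the ratio is reported as ">threshold" rather than a float.

## Evidence integration (sdcall)

Each analysis contributes evidence lines with a direction (male/female)
and a significance flag: Bonferroni-significant sex-biased RAD markers;
a ≥ 10× excess (minimum 10) of one sex's pool-specific SNPs; at least 3
hemizygous 1 kb windows in either orientation; a directed k-mer call.
The final call is XY when at least one significant male-directed line
is unopposed by any significant female-directed line (ZW symmetric);
anything else is UNDETERMINED, with an explicit conflict flag when both
directions are significant. Conflicts are never auto-resolved. Carrier
association is reported alongside but kept separate from genome-wide
signal, so "marker present but unlinked" populations are representable.
A locus-size estimate is attached whenever RAD evidence and a
restriction-site density are available.

## Synthetic populations (simpop)

The generator emulates the study design the inference targets: a
uniform-composition random reference; a sex locus planted on the
heterogametic haplotype, either a hemizygous insertion (novel sequence,
scrubbed of the restriction motif except for explicitly planted sites,
so the RAD locus count stays controlled) or a stretch of fixed
differences at a per-base divergence; diploid individuals with private
SNPs at per-base rate θ; phenotypic sex flipped from genotypic sex with
probability r (sex reversal); single-enzyme RAD reads (SbfI motif, one
locus per motif occurrence per strand, per-copy depth Poisson(mean/2),
uniform substitution errors); pooled per-site counts with Poisson site
depth and reads drawn uniformly over pool chromosome copies, which
yields the ~half-depth signature over hemizygous sequence
automatically; and per-pool canonical k-mer tables.

Default study conditions are 20 males + 20 females, 30× RAD and pool
depth, θ = 0.001, substitution error 0.001 and Poisson depth (the
emulated studies do not publish their libraries' error or depth
profiles, so these are plain, uncalibrated stand-ins), r = 0 unless a
scenario says otherwise. Validation scenarios use a 5 Mb genome with a
100 kb insertion — scaled-down but structurally faithful to a small
teleost genome with a ~140 kb sex locus; the null-calibration scenarios
use 1 Mb and 10+10 individuals across 20 seeds.

k-mer tables deserve one note: counting the pool's chromosome-copy
multiset directly gives per-k-mer counts equal to copy number (20 for a
Y-limited k-mer in a 20-male pool), which can never clear a ">25 in one
sex" read-count filter. The generator therefore emulates read-based
counting by drawing observed counts as Poisson(multiplicity ×
`depth_per_copy`), with `depth_per_copy = 2.5` — lane-scale pooled
sequencing, ~100× aggregate coverage over 40 copies. Raw multiset
counts are available with `depth_per_copy=None`. Private SNPs are not
propagated into k-mer tables (their contribution is a thin spread of
low-count k-mers that the occurrence filter removes).

Randomness derives from one master seed; each stage draws from a stream
keyed by a stable hash of (seed, stage name), so stages can be rerun
independently and all outputs are byte-identical for a fixed seed.
Streams that touch the two sex groups are keyed by *carrier status*
rather than sex label, which makes an XY scenario and its ZW mirror
(same seed, sexes exchanged) produce identical carrier-group data —
polarity symmetry holds exactly, not just statistically, and the tests
assert it as equality.

What the generator does *not* emulate — recombination, demography,
indels, GC-biased or duplicated coverage, quality-score structure,
alignment artifacts — bounds what passing tests show: recovery and
calibration results demonstrate the statistics behave correctly under
their own model assumptions, not robustness to real-library artifacts
such as mapping bias or PCR duplication.

## Degenerate inputs and numerical conventions

Zero-margin association tables → degenerate, p = 1. Sites with an
uncovered pool → skipped, counted as uncovered. Zero genome-wide male
coverage → the hemizygous scan refuses to run (no baseline). Empty
evidence lists → error. A k longer than every sequence → empty table
with a warning from the counter, an error from the simulator (which
knows its sequences). Internally all coordinates are 0-based half-open;
emitted text formats are 1-based inclusive except BED.

## Known limitations

- Marker identity is exact sequence equality; a single sequencing error
  creates a new (low-depth) marker. The depth-10 presence threshold
  absorbs this, but sensitivity decays at low coverage.
- The sex-specific SNP rule and the SNP-excess/hemizygous-window
  evidence thresholds are explicit conventions where published
  pipelines are silent; all are configurable and logged.
- FST window significance is not assessed (descriptive only).
- The k-mer counter is in-memory and single-threaded; it is sized for
  tens of megabases, not full vertebrate genomes.
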