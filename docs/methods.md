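# Methods

This note documents the models behind `palemapper`, the defaults and why
they were chosen, what the simulators do and do not emulate, and the
numerical conventions. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Cross and pooled-sequencing simulator

An F2 cohort descends from two fully homozygous parents. Each individual
is the sum of two independent gametes; each gamete is generated under the
Haldane model: the crossover count on a chromosome is Poisson with mean
equal to the chromosome's genetic length in Morgans, crossover positions
are uniform, there is no interference, and chromosomes assort
independently. This is the simplest standard recombination model;
crossover interference changes nothing at the 2-Mb bin resolution the
mapping operates on. The physical↔genetic map is uniform per chromosome
(default 1.5 Morgans per chromosome).

One biallelic causal locus determines the true phenotype class: mutant
iff the individual carries dosage 2 of the mutant parental allele. An
optional `misclassification_rate` (default 0, because phenotype classing
by eye can mislabel plants) flips the observed class independently per
plant.

Pooling is emulated at the allele-count level, not the read level. For a
pool of n plants the true frequency at a marker is (Σ dosages)/(2n);
sequencing depth is Poisson(`mean_depth`), and the alt count is
Binomial(depth, p′) with p′ = p(1−e) + (1−p)e for base-error rate e.
When `overdispersion_rho` > 0 the success probability is first drawn from
a Beta with mean p′ and intra-class correlation rho (beta-binomial) —
this single knob stands in for the extra variance of pooled RNA-seq,
where individuals contribute unequal transcript amounts. Expression-level
variation is deliberately not modelled read-by-read: the downstream
inference consumes only pooled allele frequencies.

Null designs (`causal_chrom=None`) have no phenotype signal, so the two
bulks are disjoint random subsets of the cohort.

### Default study conditions

* 565 F2 plants, bulks of 100 + 100, mean pooled depth 50×, base error
  0.01 — the pooling design of the motivating experiment.
* Desk-scale genome: 7 chromosomes × 50 Mb. Full-size plant genomes are
  unnecessary for exercising the 2-Mb binning regime and would push
  the full-pipeline tests from seconds to minutes.
* Marker density 2.5 per Mb (one marker every 400 kb). This yields
  exactly 5 markers per 2-Mb bin, matching the region detector's
  per-bin occupancy floor (`min_variants_per_bin = 5`); a sparser grid
  would leave every bin under-populated by construction.
* The causal marker is inserted into the marker grid if not already on
  it, with a G→A lesion (the EMS signature); other markers get random
  ref/alt pairs.
* Random numbers: one seeded `numpy` generator per operation call;
  `pool_and_sequence` derives a distinct stream from the same config
  seed so cohort and sequencing noise are independent but jointly
  reproducible. Identical config + seed gives bit-identical output.

## Pooled allele-frequency mapping

Per variant and pool, AF = alt depth / total depth; variants with fewer
than `min_depth` (default 10) reads in either pool are excluded with a
recorded reason — a downstream analogue of upstream read-quality
filtering, and the point where division-by-zero depths are ruled out.
The segregating-variant filter retains a variant iff AF > 0.1 in both
pools and AF < 0.9 in the wild-type-like pool, all strict inequalities.

Retained variants are aggregated in fixed-width bins (default 2 Mb,
0-based half-open; a 1-based position p maps to bin ⌊(p−1)/width⌋). The
per-bin statistic is the unweighted arithmetic mean of per-variant AFs
(a median is available); `frac_high_mut` records the fraction of
variants at or above `high_threshold` (default 0.9). Empty bins are
emitted with NA means so tracks are complete.

A bin *qualifies* when it holds ≥ `min_variants_per_bin` variants, its
mutant-pool mean AF is strictly above `af_threshold` (default 0.5) and
its WT-pool mean strictly below it. A *candidate region* is a maximal
run of ≥ `min_bins` (default 2) consecutive qualifying bins on one
chromosome **whose peak bin mean reaches `high_threshold`**. The peak
requirement is essential: at unlinked markers both pool AFs are
symmetric around 0.5, so roughly a quarter of bins qualify by sampling
noise alone and runs of them occur in every genome-scale dataset; the
near-fixation peak is the actual signature of a causal interval and
reduces the false-positive rate to essentially zero at default depth
(verified by the null-simulation test). Region boundaries are the
outermost retained-variant positions inside the run — base-pair-precise
limits, not bin edges. Regions are ranked by peak bin AF, ties broken by
run length, then chromosome order.

Known behaviour: with a recessive locus on a 1.5-Morgan chromosome the
expected mutant-pool AF (1 − r, with r the recombination fraction) stays
above 0.5 along the *entire* causal chromosome, so detected regions are
wide at desk scale and — because deeper sequencing removes the noise
dips that truncate runs — do **not** shrink monotonically with depth
under this detector. Localization precision comes from the peak bin, and
ranking, not from region width.

## Variant-effect annotation

Coordinates entering the annotator are always genomic; the CDS offset is
recomputed from the gene model (intervals 1-based closed, minus-strand
CDS counted from the highest genomic coordinate), which removes the
ambiguity of "position from the start codon" statements that may or may
not include introns. One transcript per gene; standard nuclear genetic
code; VCF alleles are complemented for minus-strand genes before codon
substitution; a reference-allele mismatch against the modelled CDS is a
data-integrity error, not a call. Start-codon changes are reported as
consequences of codon 1 with a warning. Labels use one-letter amino
acids ("R298K"); a three-letter renderer ("Arg298Lys") is provided.
`is_ems_type` flags G→A/C→T pairs; because complementing maps G→A to
C→T, the flag is strand-invariant.

The gene *fixture* generator builds ATG + non-stop filler codons + TAA,
applies requested codon substitutions (premature stops are an error
unless explicitly allowed), and inserts `GT…AG` introns after stated CDS
offsets, so genomic and spliced coordinates differ by construction.
Fixtures are synthetic stand-ins: the true exon/intron structure of any
real gene is not reproduced.

## Segregation and phenotype statistics

The segregation test is the plain Pearson goodness-of-fit statistic
Σ(O−E)²/E against a 3:1 expectation, df = 1, no continuity correction
(the convention for segregation ratios; Yates is available behind a
flag). The two-group comparison defaults to the pooled-variance
Student's t with Welch available; groups that are exactly constant give
t = 0/p = 1 when equal and a warning plus the limiting p → 0 when not —
legal simulator configurations include sd = 0.

Percent-of-control is 100 × mean_test / mean_control per pigment column,
reported unrounded and rounded half-up; computations never run on
rounded intermediates. The chlorophyll a/b ratio of a genotype is the
ratio of column means; when per-replicate values are available the mean
± sd of per-replicate ratios is also reported, since published tables
are typically computed that way before rounding.

The phenotype simulator draws quantitative traits (default Fv/Fm:
mutant-like 0.81 ± 0.02, WT-like 0.74 ± 0.02) from the *observed* class,
i.e. the class a phenotyper would act on.

## Load-cell simulator and water-balance analytics

The simulated system weight is tare + soil water + plant fresh weight.
Transpiration follows a half-sine diel profile inside the daylight
window (default 06:00–18:00), scaled by the genotype multiplier and
current fresh weight, and is zero at night; the default midday rate is
0.025 g water · g plant⁻¹ · min⁻¹, which with the default 5-g seedling
gives realistic double-digit-ml daily totals. Fresh weight increases by
`growth_rate` (default 1.5 g/day) as a step at midnight — keeping the
within-day weight derivative equal to the transpiration sink exactly, at
the cost of a small negative artefact in night-time rates (≈1 g against
hundreds of ml of daily transpiration; quantified by the conservation
tests). Irrigation is nocturnal (default 02:00): refill to pot capacity
(well-watered) or a fixed fraction (default 0.8) of the plant's own
previous-day transpiration (feedback drought). If the soil store would
go negative, transpiration is clipped and the run flagged as terminal
drought. All ground truth (per-interval sink, irrigation volumes, daily
totals, fresh weight, a dry weight equal to `biomass_per_water` × total
transpiration) is recorded for exact bookkeeping checks. Not emulated:
weather/VPD forcing beyond the fixed diel template, soil evaporation
(mulched pots), and sensor drift — so passing tests demonstrate correct
accounting, not robustness to those real-world effects.

The analytics mask any interval whose weight rises by more than
`jump_threshold` (default 2 g — events are tens of g) plus one guard
interval on each side, compute rate_i = −ΔW/Δt ÷ FW, sum unnormalized
losses per day over intervals *starting* inside the daylight window
(end exclusive; day boundary local midnight), and flag days with > 20 %
masked daylight intervals as low-confidence. Negative interval losses
from noise are retained by default (unbiased daily sums); `clip_negative`
trades bias for non-negativity. WUE uses full-day cumulative water, while
daily-rate plots use the daylight window only. Water density is 1 g/ml.

When plant fresh weight is not recorded, it is estimated from daily
pre-dawn (04:00–05:00) system weight minus tare minus an assumed soil
water baseline, linearly interpolated between days. This estimator is a
stated, testable replacement for undocumented commercial-platform
internals; it assumes the soil store returns to a repeatable pre-dawn
level and is therefore only meaningful under refill irrigation.

## Numerical conventions

* VCF/GFF3 positions 1-based closed; BED and bins 0-based half-open;
  conversions centralized in `formats.to_zero_based_start` /
  `to_one_based_start`.
* All threshold comparisons in the segregating filter and bin
  qualification are strict; exact-0.5 bins never qualify.
* Region ranking ties break deterministically (run length, then
  chromosome input order).
* Rounding of reported percentages is half-up (ties away from zero),
  with unrounded values always retained.

## Problem sizes

The test suite and acceptance checks run the full pipeline at the
desk-scale genome (875 markers, 565 plants, 20 seeds ≈ 3 s), enumerate
all ~3,600 SNVs of a 400-codon fixture against a protein-space oracle,
compare the region detector with exhaustive run enumeration on 200
random landscapes of ≤ 100 bins, and use 10,000 vectorized replicates
for the χ² type-I-error calibration.
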