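# Methods

## Signal model and assumptions

Every computation rests on a two-population mixture at each genomic locus:
a fraction *f* of cells (the *overall cellular fraction* — tumor purity ρ
times the cancer-cell fraction c_k of the clone carrying the event) has
allele-specific copy state (n_T, n_B); all other cells are diploid
heterozygous (2, 1). This gives

* expected log2 ratio `log2((2(1−f) + f·n_T)/2)` and
* expected BAF `((1−f) + f·n_B) / (2(1−f) + f·n_T)` at germline-heterozygous
  loci.

Assumptions: events of distinct clones occupy disjoint genomic territory
(nested subclones are an explicit opt-in whose fraction algebra is a
last-writer-wins simplification); sex chromosomes are excluded because BAF
expectations there depend on sex; no matched normal is available, so
germline heterozygotes are approximated by the BAF window [0.03, 0.97].
Coordinates are 1-based inclusive everywhere (SEG convention).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `footprint_fraction` | 0.01 | minimum fraction of the analyzed autosomal span a fraction cluster must cover to count as a clone; 0.005 is the sensitivity setting |
| `delta_f` | 0.08 | clustering tolerance on the fraction axis, ≈3× the empirical SD of fitted f for a 1%-footprint clone at default noise |
| `tau_log2r` / `tau_mbaf` | 0.15 / 0.58 | aberrance gates on segment medians; 0.58 corresponds to cnLOH at f = 0.16 |
| `min_probes` | 50 | ≈0.02% of a 220k array — keeps the sub-1% footprint regime observable |
| `max_total_copy` | 4 | copy-state grid cap; higher states are partially degenerate with lower states at higher fraction (see tie-breaks) |
| `mono_if_cc_le` | 0 | Mono-CC means CC = 0; configurable because other cohorts have used CC ≤ 1 |
| `seg_penalty` | 10 | change-point acceptance threshold multiplier (×log n, z-scaled squared units) |
| fit weights | 1 : 4 (log2R : mBAF) | the mBAF median over many heterozygous probes is the quieter channel |

The fraction grid runs 0.01–1.00 in 1% steps, matching the 1% granularity
of the footprint convention.

## Segmentation

Per chromosome, recursive binary splitting on the bivariate
(log2R, mBAF) series minimizes pooled within-segment sum of squares; a
split is accepted when it reduces the cost by more than `penalty·log(n)`.
Channels are median-centered and scaled by their genome-wide median
absolute deviation (floored at 1e-3 so the zero-noise limit is finite;
centering keeps the cumulative-sum cost arithmetic well conditioned).
Adjacent segments whose medians differ by less than 0.05 (log2R) and 0.02
(mBAF) are merged back; only segments with ≥ `min_probes` probes are
emitted, with median summaries (medians, not means, for robustness to
FFPE outliers). A segment's mBAF is absent when it has fewer than 10
informative probes; such segments can still be gated and fitted on log2R
alone. This is a deterministic replacement for vendor segmentation, not a
re-implementation of it; equivalence with any vendor's settings is not
claimed.

## Copy-state and fraction fitting; tie-breaks

Aberrant segments get an exhaustive grid search over all states with
n_T ≤ 4 (excluding the normal (2,1)) × f ∈ {0.01,…,1.00}. Some state pairs
are exactly signal-degenerate — e.g. (4,2) at f matches (3,1) at 2f in
both channels — so ties are broken deterministically: smaller |n_T − 2|,
then larger n_B, then smaller f. Residuals are rounded to 1e-12 before the
argmin so that exact ties resolve by this order rather than by float dust.
The average copy number is clamped at 0.05 inside the grid evaluator so
the homozygous-deletion corner (n_T = 0, f → 1) stays finite; the public
closed-form functions raise on the exactly undefined point instead.

Fraction clustering is a single ascending sweep: segments sorted by fitted
f (ties by genomic position), a new cluster opened when the next f is more
than `delta_f` from the running length-weighted centroid. CC is the count
of clusters whose summed member length reaches the footprint, with the
**analyzed autosomal span** (probe-covered, recorded in every report) as
denominator rather than the full genome.

## Synthetic data

The generator emulates an FFPE-grade 220k-probe array: probes uniform per
autosome (GRCh38 lengths), heterozygosity 35%, BAF ~ Beta(μκ, (1−μ)κ) with
κ = 60 at heterozygous loci and a random phase (which parental allele is
"B" is arbitrary; mirroring folds the two bands together), homozygous loci
at Beta-centered 0.02/0.98 with their own concentration κ = 2000 (real
homozygous clusters are far tighter than heterozygous ones — a shared
concentration would leak homozygous probes through the informative window
and bias segment mBAF upward), and log2R Gaussian with σ = 0.25. Setting
σ = 0 and κ = ∞ renders expected values exactly (the zero-noise shortcut
used by exactness tests). Output is byte-identical given the seed.

`architecture_from_fractions` assigns each clone one event on its own
chromosome, cycling through deletion, gain and cnLOH states but
substituting a detectable state (cnLOH, deletion or two-copy gain) when
the preferred one would fall below both aberrance gates at that clone's
fraction — an intrinsically invisible event does not represent a callable
clone. Truth CC counts distinct rendered fractions (rounded to 0.01) among
events whose aggregate span reaches the footprint, mirroring the
pipeline's counting semantics.

Cohort simulation draws Mono/Poly membership (Poly prevalence 59/74),
CC values from the observed Mono/Poly histograms, exponential event times
with group-specific hazards (baseline from a 69.1% 5-year event-free rate
in the Mono group; Poly hazard = baseline × 2.68 for EFS, × 1.27 for OS)
and independent uniform censoring over (0, 2989] days. The printed Poly
5-year OS (62.8%) is not exactly consistent with proportional hazards
given the Mono rate and HR 1.27; the simulator encodes the HR, so its
Poly OS settles near 59%. Probe-level rendering of every cohort member is
an opt-in flag: the survival-recovery analyses need only the clinical
table, and rendering thousands of 220k-probe samples would add nothing
but runtime.

**What the simulator does not emulate:** GC waves and probe-specific
effects (noise is i.i.d.), mutation/SNV data, nested clone algebra, and
array failures from degraded DNA. Passing recovery tests therefore shows
the estimator is correct under the stated mixture model with realistic
noise magnitudes — not that it is robust to every FFPE artifact.

## Cohort statistics

2×2 exact tests use the hypergeometric probability-mass rule (scipy's
convention, relative tolerance 1e-7); r×c tables use the Freeman–Halton
generalization by full enumeration over fixed-margin tables (capped at
total n ≤ 200), implemented here because scipy has no r×c exact test.
Mann–Whitney is enumerated exactly for n ≤ 20 (valid under ties) and uses
the tie-corrected continuity-corrected normal approximation otherwise.
Kaplan–Meier carries Greenwood variance; Cox models use lifelines with
Efron tie handling (the default of major survival software), flagging
monotone-likelihood non-convergence instead of reporting garbage. The
minimum detectable hazard ratio is the Schoenfeld formula
`exp((z_{1−α/2}+z_{power}) / sqrt(D·p(1−p)))` with every input explicit —
the event count D is a required argument, not an assumption. CC-histogram
summaries report both SD conventions (n and n−1 denominators) because
printed tables rarely state which they used.

## Problem sizes and numerical choices

The recovery analyses run 50 pipeline executions at the full 220k-probe
default (cycling 1-, 2- and 3-clone architectures with fraction gaps
≥ 0.16 and per-clone footprints of 2.5%), and an exhaustive zero-noise
grid (all 1–3-subsets of f ∈ {0.2, 0.4, 0.6, 0.8}) at 60k probes — the
zero-noise check is scale-free above the min-probes floor. The footprint
monotonicity property is checked on 100 random 20k-probe samples for the
same reason. Cox recovery uses one 2000-patient cohort in the test and
the mean of five replicates in the acceptance script (Monte-Carlo error
reduction; the injected value is unchanged). Kaplan–Meier 5-year summaries
use an 8000-patient cohort so the small Mono group is not noise-dominated.

## Known limitations

* Purity and ploidy are never globally optimized; a tumor whose only
  aberration is a whole-genome doubling is invisible to the state grid.
* Fraction clustering is 1-D and greedy; two clones closer than `delta_f`
  in cellular fraction merge into one cluster by construction.
* Sub-threshold events (e.g. a single-copy gain below ~22% cellular
  fraction) fall under the aberrance gates and cannot contribute to CC.
* The per-cluster aggregate footprint convention (rather than
  per-segment) is a choice; it reproduces the documented 1% → 0.5%
  sensitivity behavior.
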