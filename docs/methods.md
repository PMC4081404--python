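# Methods

## Scope and model

`nucperiod` analyses DNA sequence variation relative to nucleosome
positions.  The observable units are 147 bp nucleosome-core fragments
("n147"), classified as intergenic or intronic when the fragment plus a
±50 bp flank lies wholly inside one contiguous annotated region of that
class and outside any user-supplied mask.  Three per-offset statistics are
computed across the fragments, all dyad-symmetrized: dinucleotide
frequency, polarized lineage-specific divergence, and the Δπ skew index of
the site frequency spectrum.

### Coordinate and symmetrization conventions

All intervals are 0-based half-open; GFF input is converted on read.
Offsets are negative and increase toward the dyad.  Each fragment
contributes two half-observations: the top strand at offsets −73..0 and the
reverse complement of the top strand at offsets 0..+73.  The dyad base
(offset 0) belongs to both halves, so dinucleotide columns −73..−1 exist
and the column −1 dinucleotide spans the dyad; mononucleotide statistics
report columns −73..0 with offset 0 averaged over both halves.  Flanking
sequence is treated identically (left flank as-is, right flank
reverse-complemented).  Substitution pathways switch at the dyad: genomic
C→T on the right arm counts toward G→A at the mirrored column.  A
consequence worth noting: because both halves of every fragment are always
pooled, re-running any profile on the reverse-complemented genome with
mirrored intervals reproduces it exactly (strand involution invariance).

### Weightings

*per-n147* counts every half-observation once, weighting genomic sites by
their recurrence across overlapping fragments (an occupancy weighting).
*per-site* divides each occurrence of a genomic site by its total number of
covering half-observations, so every site contributes total weight exactly
1; the dyad base of a single fragment counts as two half-observations of
weight ½ each.  On non-overlapping fragment sets the two weightings
coincide, which is tested.

### Trims, smoothing, masking

Five bp at each fragment end are trimmed from rate and Δπ profiles (nuclease
cleavage bias); for large-scale (±1 kb) profiles, columns within 5 bp of the
fragment edge are masked.  Fine-scale display smoothing is a 5-column
running average with weights (0.125, 0.25, 0.25, 0.25, 0.125); large-scale
smoothing averages the flank (50 equal-weight columns) and core (30
columns) segments separately after the edge trim.  At segment edges and
around masked columns the kernel is renormalized over the available taps —
so a constant profile is exactly preserved, and interior sums are preserved
to 1e−12.  Correlations (the pathway–dinucleotide matrix) always use
unsmoothed profiles; smoothing is presentation-layer.

### Polarization

Standard mode: the ancestral base is the sibling-species base when at least
one of the two outgroups agrees with it; stringent mode requires both.
Missing data (N) at any required species makes the site unpolarizable, a
value rather than an error.  Stringent-polarizable sites are a subset of
standard-polarizable sites, and swapping the two outgroups never changes
the call (both properties are tested).

### Δπ

With derived count i among n quality-passing calls, the per-SNP
heterozygosity is h(i,n) = 2i(n−i)/(n(n−1)) (the n/(n−1) unbiased form).
Under the neutral equilibrium spectrum G_n(i) ∝ 1/i the expectation of h is
exactly 1/a_n, so Δπ(i,n) = h − 1/a_n is centered at 0 under neutrality;
the centering and the closed-form neutral variance are guarded by
brute-force enumeration for every n in 4..500 (to 1e−12) and by a 10⁶-draw
Monte-Carlo check at n = 34.  Heterogeneous sample sizes are combined by
weighting each class mean by S_n/Var_n; the standard error is
(Σ w_n)^−1/2.  Supported SNP filters: a sample-size window (e.g. 32–34),
folded singleton removal (min(i, n−i) = 1), an ascertainment filter keeping
sites where the experimental strain carries the ancestral allele, and
exclusion of positions with more than one segregating pair (pathway labels
are biallelic).

### Period estimation

Profiles have masked columns, so spectral power is computed with the
Lomb-Scargle periodogram on the unmasked columns after detrending (mean,
linear, or subtraction of a 601-column running mean for large-scale
profiles, which strips structure slower than ~600 bp such as the broad
AT-content skew around arrays).  The dominant period is the argmax over a
2000-point period grid with quadratic interpolation; the prominence is the
peak variance-normalized power, which is invariant under positive rescaling
of the profile.  Significance uses a seeded column-shuffle permutation null
(200 shuffles by default); the pipeline flags a profile as periodic only
when its prominence exceeds every permutation, a deliberately family-safe
rule given the ~15 profiles per run.  No analytic p-values are claimed; the
estimator is validated on synthetic signals only (±0.5 bp at the helical
scale, ±10 bp at the repeat scale).

## The synthetic generator

The generator emulates the data-generating process the analysis assumes:

* **Genome.** Nucleosome arrays on one chromosome; each array carries
  `nucleosomes_per_array` cores at the repeat spacing (default 180 bp =
  147 bp core + 33 bp linker) and is labeled alternately intergenic or
  intronic (slightly different background composition, so class contrasts
  are exercised).  Consecutive arrays are separated by a nucleosome-free
  gap of one repeat plus one linker, keeping the translational phase
  continuous genome-wide (cross-boundary core spacing is exactly two
  repeats).  Sequence is sampled left to right from the class background
  composition with multiplicative reweighting: completing an AA or TT
  dinucleotide whose start sits in a core at dyad offset d is scaled by
  1 + A·cos(2π(|d|−φ)/T) (defaults A = 0.3, T = 10 bp, φ = 5 bp, putting
  peaks at the superhelix locations |d| = 5, 15, …, 65), GC completion by
  the antiphase factor, and G/C bases outside cores by 1 + linker_gc_boost
  (default 0.3).  Amplitudes that would drive any weight negative are
  rejected.
* **Divergence.** Star phylogeny (focal, sibling, two outgroups at 2.5×
  branch length).  Default rates per focal/sibling branch: G→A = C→T =
  0.05, A→G = T→C = 0.03, transversions 0.012 — a GC→AT transition excess
  of the kind seen on the focal lineage this emulates.  At most one
  substitution per site per branch, probability 1 − e^(−rate), matching the
  infinite-sites assumption behind polarization.  Focal-lineage G→A/C→T
  rates inside cores are multiplied by 1 + β·cos(2π(|d|−φ)/T) and A→G/T→C
  by the antiphase factor.
* **Polymorphism.** Each site segregates with probability θ (default 0.02,
  a realistic fly-scale diversity); the derived base is a transition with
  probability 0.7.  Derived sample counts follow G_n(i) ∝ 1/i when the
  site's scaled selection coefficient γ is 0; otherwise the population
  frequency is drawn by inverse-CDF on a 10⁴-point grid from the
  Poisson-random-field stationary density
  f(x) ∝ (1−e^(−γ(1−x)))/(x(1−x)(1−e^(−γ))) weighted by the probability of
  segregating in the sample (the unweighted density is non-integrable at
  x → 0), then i ~ Binomial(n, x) conditioned on segregating.  γ → 0
  reduces exactly to the neutral sampler.  |γ| > 50 is rejected as an
  overflow guard.  Positional selection is expressed as
  γ(d) = γ + γ_amp·cos(2π(|d|−φ)/T) inside cores.
* **Fragments.** Each core emits `depth` fragments, shifted by a rounded
  Normal(0, jitter_sd) with lengths drawn from a configurable range, dyad
  kept centered; fragments running past the contig are dropped and logged.

What the generator does **not** emulate: linkage disequilibrium or
recombination (sites are independent, as the Δπ aggregation itself
assumes), demography, MNase cleavage sequence bias beyond uniform edge
jitter, indels and alignment error, heterochromatin, and coverage biases
correlated with GC.  Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model — not robustness of the
biological conclusions to those real-data complications.

## Problem sizes and numerical choices

The benchmark and test simulations use desk-scale sizes chosen to give
clear statistical resolution: 2000 cores (~0.77 Mb) for helical-period and
phase-recovery checks, 500 ten-nucleosome arrays (~1.1 Mb) for the
repeat-scale period, 10⁵–10⁶ draws for SFS sampling checks, and 300 cores
for unit-test fixtures.  Phase alignment between a smoothed profile and the
generator's enrichment cosine is measured as the correlation-maximizing
integer lag within ±5 columns, a robust equivalent of matching individual
peak positions at these SNP densities.  Degenerate inputs follow explicit
rules: zero ancestral count masks a rate column; fewer than 10 shared
unmasked columns refuses a profile correlation; fewer than 3 regions or
windows refuses a rank correlation; fewer than 3 cycles of the largest
candidate period refuses a period estimate.  Quantile bins differ in size
by at most one, with ties broken by genomic order.  All randomness flows
from explicit integer seeds through numpy Generators; identical seeds give
byte-identical outputs (tested by hashing entire run directories).

## Known limitations

Real-mode inputs must fit in memory (whole-genome uint8 arrays); no BAM or
MAF parsing — fragments arrive as BED and the four-species alignment as a
per-site TSV, by design.  The Δπ variance model assumes free recombination
between SNPs; with linkage the reported standard errors are anti-
conservative.  The period estimator reports a single dominant period and is
not a multi-component spectral decomposition.  Occupancy-correlation
routines follow fixed filter conventions (≥50 of 147 bases polarizable per
region; 500 bp windows with ≥166 polarizable bases and ≤250 reference Ns)
and are not yet configurable per call.
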