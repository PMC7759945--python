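# Methods

This note records the statistical model behind each stage of the package,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical choices a maintainer would want to
know about. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Time conventions

Clock times map to the unit circle by θ = 2π·(hour-of-day/24), midnight at
θ = 0; all internal maths is in radians and user-facing summaries in clock
hours. Circular densities live on a fixed grid of G = 128 equally spaced
angles; evaluation at arbitrary angles is linear interpolation with 2π
periodicity, and integrals are trapezoidal including the wraparound
segment. Every density is renormalised to integrate to 1 (tested to 1e-6).

## Independent events

A photo is one candidate event regardless of how many conspecifics it
shows; a photo of two species is two candidates (two rows). Within each
(station, species), a greedy forward scan keeps a record only if it falls
at least one hour (default, configurable) after the previous *retained*
record — the standard pseudo-replication rule; comparing to the last
retained event rather than the last raw photo makes the filter idempotent.
The window is half-open, so a record exactly 60 min after the previous
retained one counts as independent. Records with unparseable timestamps
are rejected with a logged warning, never silently. Cross-station
de-duplication of wide-ranging individuals is deliberately not attempted:
independence is defined per camera location.

## Diel classification

The default solar schedule is 06:00/18:00 (equatorial site average);
per-record schedules can be supplied. Day is the half-open interval
[sunrise, sunset), so an event exactly at sunrise is diurnal and exactly at
sunset nocturnal. Twilight is ±1 h around either anchor and overlaps both
day and night; twilight percentages use total events as denominator.
Categories come from the unrounded nocturnal fraction p:
p ≤ 0.10 strongly diurnal, < 0.30 mostly diurnal, < 0.70 cathemeral,
< 0.90 mostly nocturnal, ≥ 0.90 strongly nocturnal — boundaries placed so
"at least 90%" is honoured inclusively on both tails. Reported percentages
round half-up to integers; classification always uses the raw fraction.

## Kernel and trigonometric-sum densities

The kernel estimator is a mean of von Mises kernels centred at the events.
Its concentration comes from Taylor's circular rule of thumb,
κ_h = [3n κ̂² I₂(2κ̂) / (4√π I₀(κ̂)²)]^{2/5}, with κ̂ the single-von-Mises
maximum-likelihood concentration of the sample (Best–Fisher start, Newton
refinement; Bessel ratios computed with exponentially scaled `ive` so large
κ never overflows). The `adjust` argument follows base-R `density()`
semantics: the kernel concentration is κ_h/adjust, larger values smoothing
more. Δ̂₁ uses adjust 0.8 and Δ̂₄ adjust 1.0, the values recommended in the
overlap-estimation literature. Known limitation: for sharply bimodal
schedules the single-von-Mises κ̂ underestimates concentration and the
plug-in oversmooths, which biases peak-dependent quantities (activity
level up, low overlaps up); this is a property of the standard rule, not of
the implementation.

The trigonometric-sum density estimates Fourier coefficients up to order 3
by empirical trigonometric moments, clips negative values and
renormalises. This moment-based fit stands in for full non-negative
trigonometric-sums maximum likelihood deliberately: the estimator is used
only as a sample-size adequacy cross-check against the kernel fit, for
which the package reports the total-variation distance and leaves any
threshold to the user (no adequacy cutoff is defined in the source
methodology).

## Hermans–Rasson uniformity test

The statistic is the pairwise form
T = Σᵢⱼ [ |π − |θᵢ−θⱼ|| − π/2 − 2.895·|sin(θᵢ−θⱼ)| ].
The minus sign on the |sin| term is essential: both terms shrink under
uniformity and grow under unimodal *and* axial/bimodal alternatives, which
is what gives the "new" Hermans–Rasson test its power against the bimodal
schedules duikers actually show (with a plus sign the test cannot reject
for near-axial bimodality; this was verified by simulation during
development). By default T is evaluated through its exact cosine-series
decomposition T = −β(2/π)n² + Σₖ cₖ(Cₖ² + Sₖ²) truncated at 64 harmonics
(cₖ = (4/π)/k² for odd k, +β(4/π)/(k²−1) for even k; Cₖ, Sₖ the sample
trigonometric sums), which costs O(nK) instead of O(n²) and is applied
identically to observed and null samples, so the Monte-Carlo p-value is
unaffected by truncation. The O(n²) direct form is kept and cross-checked
in the tests. The null distribution is simulated from uniform samples of
the same n (default 1000 replicates); p = (1 + #{T_null ≥ T_obs})/(1 + B),
the standard conservative Monte-Carlo estimator.

## Circular median, rose bins, activity level

The circular median minimises the mean circular absolute deviation
π − |π − |θ − φ||; candidates are a minute grid plus the data points, and
ties resolve to the smallest angle. Rose bins are relative frequencies in
24 hourly class intervals. The activity level is 1/(2π·max f̂) of the
kernel fit — the ratio of mean to peak detection rate, i.e. the proportion
of the cycle spent active under the assumption that animals photographed
are active and that peak-rate activity is continuous. Its confidence
interval is an ordinary nonparametric bootstrap (events resampled with
replacement, bandwidth refit each time, percentile 2.5/97.5); percentile
intervals can in principle exclude the point estimate, which is flagged
rather than corrected.

## Temporal overlap

Δ̂₁ integrates min(f̂, ĝ) on the shared grid; Δ̂₄ averages min(1, ĝ/f̂) over
the first sample and min(1, f̂/ĝ) over the second, with densities floored
at 1e-12 inside the ratios. The estimator switches from Δ̂₁ to Δ̂₄ when both
samples reach 75 observations. Estimates are clipped to [0, 1]; identical
samples give Δ̂₄ = 1 exactly. Strength bands: low ≤ 0.5 < moderate ≤ 0.75 <
strong (the only reading consistent with "strong > 0.75" and "low ≤ 0.5").

Confidence intervals use a smoothed bootstrap — resample events, jitter by
the fitted kernel, re-estimate including the bandwidth — with plain
percentile bounds (ordinary resampling behind `smoothed=False`). Known
limitation: bootstrap Δ̂ values are biased upward (smoothing enters twice),
so percentile intervals for very low or very high overlaps can sit beside
the point estimate; the package reports them uncorrected, as plain
percentile intervals.

The same-distribution test permutes pooled labels with 1 − Δ̂ as the
discrepancy. The kernel bandwidth is estimated once from the pooled sample
and shared by both densities, making the statistic a symmetric function of
the partition, so the permutation p-value is exactly valid; it also lets
each relabelling reuse one precomputed kernel matrix (column averages, no
exponentials). Refitting per-sample bandwidths on every permutation is
available via `refit_bandwidth=True`. Watson's two-sample U² (midrank tie
handling) is offered as a classical alternative, with p reported against
the standard critical-value bands 0.152/0.187/0.268 for 10/5/1%.

## Spatial co-occurrence

Presence is naive: a species occupies a station iff it produced at least
one independent event there; imperfect detection is not modelled. The
shared-station count under fixed margins is hypergeometric; p_lt and p_gt
sum P_j below and above the observed count over the support only (terms
beyond min(N₁, N₂) are identically zero), delegated to scipy's log-space
hypergeometric routines and verified in the tests against full enumeration
and a fixed-margin permutation oracle. Classification at α = 0.05;
if both tails were ever significant (a pathological margin configuration)
the smaller tail wins with a logged warning. Pairs whose rarer species
occupies fewer than 5 stations are flagged low-power but still reported.
All retained stations pooled across sites form N; *C. nigrifrons* is
excluded from pairwise analyses by default because it occupies a distinct
swampy habitat.

## Matrix association

The Mantel statistic is the Pearson (optionally Spearman) correlation of
the vectorised upper triangles; rows/columns of the second matrix are
permuted simultaneously. With S ≤ 7 labels all S! permutations are
enumerated and the p-value is exact (120 permutations at S = 5); larger
communities use seeded Monte-Carlo with the add-one estimator. The two
matrices entering the pipeline's test are the overlap Δ̂ matrix and the
standardised effect-size matrix — the only standardised spatial quantity
the pipeline computes per pair. One-sided (greater) by default, two-sided
via `alternative="two-sided"`.

## Synthetic communities and the study replica

Each species is a `SpeciesProfile`: a von Mises mixture over the 24-h
circle (components as mean hour, concentration, weight), a daily detection
rate per occupied station, a marginal occupancy probability, and a
group-size distribution. Detections at an occupied station are an
inhomogeneous Poisson process (rate × diel density) over the deployment;
a configurable burst probability appends sub-hour repeat photos that the
independence filter must remove.

Occupancy uses a sequential conditional-logit construction: species are
simulated in order, each with logit p = c_s + Σ_{t<s} z_t·ln OR(t,s), and
the intercept c_s solved by root-finding against the exact joint law of
the predecessors, so marginals match exactly. Odds ratios are exact for
every pair involving the first associated species and conditional for the
rest; the replica orders the association hub (*C. callipygus*) first so
all configured ratios are exact.

`study_replica_config()` bundles a six-species community calibrated to the
published survey summaries: 12 sites × 36 stations × 41 days (17,712
trap-nights, matching the survey's total effort under uniform
deployments); daily rates derived from the published event totals;
mixtures tuned so that population medians, day/night splits, activity
levels and the pairwise overlap structure reproduce the published
community; occupancy odds ratio 5–7 for the four positively associated
pairs and a mild 1.8 between the two commonest species. That last value
compensates a real artefact of the survey design: retaining only stations
with at least one duiker event conditions on a collider and pushes the two
commonest species toward spurious negative co-occurrence.

Two variance-reduction devices are on by default in the replica (and off
in the generic generator): each species' event total is conditioned on its
expectation (the Poisson process given its total, i.e. multinomial
allocation, with events spread over distinct days per station), and
time-of-day values are drawn by stratified inverse-CDF sampling, which
preserves the marginal diel law exactly while shrinking empirical-CDF
error from O(1/√n) to O(1/n). The reason is statistical, not cosmetic: at
the survey's smallest sample sizes (42 and 61 events) the sampling noise
of an iid circular median exceeds half an hour whenever the activity level
is in the realistic 0.3–0.5 range (peak density caps how sharp the
empirical CDF can be at the median), so a replica meant to reproduce
published medians to ±0.5 h at published sample sizes must control that
noise at the source. Consequently the replica's summary statistics sit
near their population values; what passing tests on it demonstrate is that
the *analysis pipeline* recovers the structure the generator encodes, not
that field data of this size would yield equally stable estimates.
Features of real data the generator does not emulate: within-day temporal
clustering beyond bursts, seasonal and weather forcing, heterogeneous
deployment durations, imperfect species identification, and spatially
explicit movement.

## Seeds and reproducibility

Every stochastic routine takes a seed or `numpy.random.Generator`; absent
seeds are logged. The pipeline derives named substreams from one root seed
(CRC-32 of the stage name into a `SeedSequence`), so a stage rerun with
its substream reproduces the pipeline-level output, and identical seeds
produce byte-identical CSVs (tested). Bootstrap and permutation counts
default to 1000 throughout; the calibration test suite uses 199-replicate
inner loops over ≥ 500 outer replicates, which resolves the 0.05 level
while keeping the suite fast.

## Degenerate inputs and error policy

Numerically coincident samples (mean resultant length ≈ 1) raise a
degenerate-sample error from every density-based routine; samples below
the documented minima (2 for densities, 5 for uniformity and permutation
tests, 8 for Watson, 10 for activity level) raise insufficient-data
errors. Empty event sets raise explicit empty-result errors rather than
returning empty frames. Pipeline stages tag their failures with the stage
name and retain any tables already computed.
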