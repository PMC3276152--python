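# Methods

This note records the model assumptions, parameter choices, and numerical
conventions behind `fragilemap`, and what the synthetic-data tests do and
do not establish about real array data.

## Coordinates and features

All files use BED conventions (0-based, half-open); all internal
positions are 0-based and midpoints are real-valued. Genomic features are
reduced to point midpoints immediately on load because every statistic in
the pipeline is a midpoint-to-midpoint distance; strand is ignored, as
the underlying assays (ssDNA labeling, DSB end labeling) are
strand-agnostic. Feature categories form a closed vocabulary
(`checked_origin`, `unchecked_origin`, `centromere`, `cut_site`,
`other`): "checked" origins are late/inefficient origins whose firing an
active replication checkpoint delays, "unchecked" origins are
early/efficient ones that fire in HU regardless.

## Normalization and ratio formation

QC-flagged spots are removed before anything else. Each channel is
background-subtracted per probe and divided by its genome-wide total, so
both normalized channels sum to exactly one (asserted in tests); the
per-probe ratio of the normalized channels is therefore invariant to any
uniform rescaling of either channel (laser gain, labeling efficiency).
Probes whose control net signal is non-positive cannot yield a ratio;
they are dropped and counted in the profile's normalization record, never
imputed. Dropping them *before* computing the channel totals keeps the
conservation property exact.

## Lowess smoothing

Smoothing is locally weighted linear regression (degree 1) with tricube
weights on genomic distance, zero robustness iterations, computed
independently per chromosome. The window is defined in base pairs — a
6,000 bp total span, i.e. ± 3 kb around the target probe's midpoint — not
as a fraction of probe count, so resolution is uniform along the genome
and coincides with the 6 kb proximity cutoff of the association test.
Degree 1 with tricube and no robustness pass are the canonical Cleveland
defaults; they are recorded in the profile metadata. Ratios are smoothed
on the natural scale because sites are thresholded on ratios directly
(a log2 transform can be applied upstream if desired). Numerically, the
local fit is solved in coordinates centered on the target probe via the
closed-form 2×2 normal equations; when the weighted design is degenerate
(all in-window probes at one coordinate) the fit falls back to the
weighted mean, and a probe alone in its window keeps its raw value. Local
linear regression reproduces any profile that is linear in the coordinate
exactly (to 1e-9 in tests), and the implementation is checked against an
independent O(n²) weighted-least-squares oracle at the same tolerance.

## Site calling

The significance rule is "strictly above the genome-wide median of the
smoothed profile". Genome-wide (not per-chromosome) because site totals
are counted across chromosomes; strict, so a constant profile yields zero
sites. The rule is scale-free: rescaling the profile rescales the median
with it. Sites are individual probes (probe midpoints), not merged
intervals; `merge_nearby` exists behind an off-by-default flag for users
who want regions. Peak calling — used only for cut-site positive controls
and display — is `scipy.signal.find_peaks` per chromosome with a default
prominence of 0.5 × the interquartile range of the smoothed values,
floored at 1e-6 of the profile maximum so floating-point jitter on flat
stretches can never register as a peak. The prominence rule is a declared
choice of this package and is kept out of any reproduction claims.

## Association statistics

Nearest-feature distances are exact (sorted-array search, verified
against brute force); features on other chromosomes are infinitely far,
and an empty category gives a saturated, P = 1 test rather than an error.
The 6 kb cutoff is inclusive (≤ 6000 bp). The null randomizes *site
positions*, drawing equal-sized subsets of distinct unflagged probe
midpoints uniformly without replacement — positions on the array are
distinct spots, and resampling is genome-wide, not stratified per
chromosome. The p-value is the tie-inclusive upper-tail proportion
k / n_sims with no +1 smoothing, so attainable values include exactly 0
and exactly 1. Sampling is vectorized (per simulation, the n smallest of
N uniform keys index a uniform subset) and fully reproducible from the
seed. `exhaustive_null` enumerates all C(N, n) placements when that count
is ≤ 10⁶ and is the oracle the Monte Carlo path is tested against (the
null is hypergeometric in disguise, which provides a second, closed-form
cross-check in the tests). The proportion test is the Pearson chi-square
on the 2×2 table with the Yates correction clamped so the statistic never
goes negative; it matches R's `prop.test` to full precision.

## Synthetic data

The generator emulates the measurement layer only, not the biology: a
probe grid at chosen spacing (defaults: 290 bp ≈ 4x44K density on a 12 Mb
genome; a 2 × 200 kb mini genome at 500 bp for sub-second tests), a
constant-expectation control channel, an experimental channel whose
expectation is baseline × (1 + Σ peak contributions) with Gaussian or
point-mass peaks, independent mean-one log-normal noise per channel with
coefficient of variation `noise_cv` (default 0.1, a typical per-spot CV
for two-color arrays), a constant additive background (default 50
fluorescence units against a 1000-unit control level), and a 1% flagged
fraction. Peak amplitude defaults to 6-fold with σ = 3 kb, chosen as
clearly detectable but not saturating; the magnitude of real breakage
enrichment is not published, so amplitudes are free parameters of the
emulation, not calibrated values. Not modeled: dye-swap or print-tip
spatial artifacts, probe-sequence affinity, saturation, or any mechanism
of fork movement — so passing tests demonstrate that the *pipeline*
recovers planted structure under realistic noise, not that real arrays
have these statistical properties.

## Full-scale emulation (acceptance script)

`scripts/acceptance.py` uses the 16-chromosome budding-yeast layout
(~12.1 Mb, ~41,600 probes at 290 bp), 210 checked and 105 unchecked
origins, breakage peaks at every checked origin, and 10,000-draw
association tests. Two placement rules keep the emulation faithful to
the scenario it represents. First, unchecked origins are rejection
sampled at least 25 kb from every checked origin: the two categories
emulate temporally distinct origin classes, and if an "unchecked" origin
sat inside a checked origin's enrichment footprint the category contrast
would be confounded by construction. Second, in the shifted-fork
scenario each peak moves 25 kb toward whichever side lies farther from
all checked origins — migration proceeds into inter-origin territory; a
randomly directed shift would frequently land a peak on a *neighboring*
origin (mean inter-origin spacing here is ~57 kb) and turn the intended
negative control into a positive association.

## Null calibration test sizes

The uniformity check of the randomization p-value (500 replicate tests
with sites drawn from the universe itself, Kolmogorov–Smirnov at
α = 0.01) uses a 3,200-probe universe with 400 sites and ~48% of probes
feature-proximal. The sizes matter: the tie-inclusive empirical p is
discrete and stochastically *larger* than uniform by up to the null
pmf's maximum, so the null count distribution must be wide enough
(here σ ≈ 9, max pmf ≈ 0.04) that this discreteness stays below the KS
critical deviation at n = 500 (≈ 0.073). With narrow counts the KS test
would reject for discreteness alone, which says nothing about the
implementation.

## Known limitations

- The above-median rule classifies ~half of all probes as "sites" on any
  continuous profile; its power in the association test comes entirely
  from where those sites sit, and interpretation of site *counts* should
  keep that in mind.
- Replicate-profile correlations on synthetic data (~0.99 at the default
  noise) are higher than typical published replicate values (~0.8–0.93),
  because the generator omits biological variability between cultures and
  array-specific spatial artifacts.
- Smoothed values are spatially autocorrelated within a window, so
  adjacent sites are not independent observations; the randomization test
  accounts for the site *count*, not for site clustering.
- The exhaustive null enumerates subsets and is intended for ≤ 10⁶
  placements; beyond that the Monte Carlo path is the supported route.
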