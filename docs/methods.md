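# Methods

This note documents the models, defaults and numerical choices behind
the `placecell` pipeline, and what the synthetic cohort can and cannot
show about real recordings.

## Analysis pipeline

**Speed and activity filtering.** Speed is the magnitude of the central
finite difference of position (one-sided at the endpoints), smoothed
with a 0.4-s boxcar by default. The smoothing window exists to keep
tracker jitter from toggling the activity cut; it is configurable and
can be disabled. Samples with speed < 3 cm/s are inactive. Each sample
owns the half-open span up to the next sample, so active + inactive time
equals the session duration exactly (the final sample owns no span, a
one-sample-period slack documented in the conservation invariant).

**Cluster-drift QC.** The exclusion rule — first-principal-component
drift of more than three standard deviations across the two sessions of
a day — needs an operational statistic. We use the difference between
the mean feature amplitude in the last and first deciles of the day's
spikes, in units of the pooled within-decile SD. This is robust to
single outlying spikes, monotone in true drift, and invariant to affine
rescaling of the feature axis. A degenerate pooled SD of zero is treated
as zero drift when the decile means agree (and as certain exclusion when
they do not). With data from a single session the check is skipped with
a warning, since drift is defined across the day.

**Pyramidal classification.** Putative pyramidal cells are slow-firing
and bursty; fast-spiking interneurons are neither. The surrogate
criteria are: mean rate ≤ 8 Hz, and mean lag of the spike
autocorrelogram within a 50-ms window ≥ 8 ms. A Poisson train is flat
over the window (mean lag ≈ 25 ms) and passes; a cell firing
predominantly in ultra-short-ISI bursts concentrates the ACG below 8 ms
and fails, as does anything above the rate ceiling. All thresholds are
keyword arguments. Units with fewer than 50 spikes are classified
"other" (too little evidence either way).

**Rate maps.** Occupancy is binned on a 2 × 2 cm grid spanning the
arena's bounding square; each active sample contributes its own span to
its containing bin. Bins wholly outside the circular wall are invalid
regardless of occupancy, as are bins sampled for less than 200 ms.
Spike positions are linearly interpolated along the trace at spike time
(nearest-sample assignment is not offered; interpolation is strictly
better at 25 Hz). Rates are spike count over occupancy on valid bins;
invalid bins carry NaN, never zero, so they cannot leak into any
statistic.

**Smoothing.** "Radius 2" is read as 2 bins (4 cm): each valid bin
becomes the mean of valid bins within Euclidean distance ≤ 2 bins (a
13-bin disk), renormalized by the local count of valid bins so edge
bins are unbiased rather than smeared toward zero. A Gaussian
alternative (σ = radius/2 bins) sits behind a keyword. Consequences of
the renormalization: a constant map is exactly preserved, smoothed
values never leave the input's [min, max], and the map mean is exactly
preserved only where the kernel never meets the mask edge (the property
test uses interior support for this reason).

**Field detection.** Fields are 4-connected components of valid bins
with rate strictly above 30% of the map's peak, kept when strictly
larger than 10 bins (≥ 11). Four-connectivity is the conservative
reading of "adjacent"; 8-connectivity is a keyword away. Detection runs
on the smoothed map; the contiguity-free "active pixel" count on the
unsmoothed map is reported separately, as the two measures answer
different questions (compact field size vs total active area). Field
sizes are reported in bins and cm² only.

**Spatial information** is computed on the unsmoothed normalized map by
default — smoothing correlates neighboring bins and inflates apparent
information — with a keyword to use the smoothed map instead. Zero-rate
bins contribute zero; a silent cell has undefined (NaN) information.

**Specificity ratio.** In-field and out-field mean rates are
occupancy-weighted (time-weighted), so the ratio equals what one would
estimate from raw spike and dwell counts. Undefined when there is no
field, no valid out-field bin, or a silent out-field.

**Stability.** Sessions are split into contiguous equal-duration
segments with edges snapped to trace sample times; segments are
half-open in time (spikes partition losslessly) and adjacent segment
traces share the boundary sample, which owns no time span in the
earlier segment, so occupancy is never double-counted. Each segment is
re-analyzed from scratch — speed filter, occupancy mask and all — and
correlations use only bins valid in both maps, requiring at least 20
shared bins and non-constant values on the shared set. Quarters are
compared as the three adjacent pairs by default (all six via keyword).
Between-session correlations use smoothed full-session maps.

**Group statistics.** Mann-Whitney U is reported as min(U₁, U₂) with
midrank ties; the p-value is the exact permutation probability when
n₁·n₂ ≤ 400 and the pooled sample is tie-free, otherwise the normal
approximation with tie correction (computed via scipy). The two-way
genotype × session ANOVA uses Type-II sums of squares (statsmodels),
appropriate for the unbalanced cell counts that arise when different
numbers of cells survive each session; with zero variance everywhere
all effects are reported as F = 0, p = 1 rather than 0/0. Bonferroni
post-hocs are protected t contrasts on the pooled residual variance,
p multiplied by the number of comparisons and capped at 1.
Observations are treated as independent cells; `aggregate_animals=True`
collapses to per-animal means first — the conservative option when
cells within an animal are correlated.

## Synthetic sessions

**Trajectory.** A mean-reverting (Ornstein-Uhlenbeck) 2-D velocity
process integrated at 25 Hz with specular reflection at the wall and a
constant outward radial acceleration scaled by `wall_bias`. Defaults:
30-min sessions, relaxation 0.5 s⁻¹, `mean_speed = 5.6` cm/s and
`wall_bias = 0.6`, calibrated by Monte-Carlo so the realized median
active speed is ≈ 5.9 cm/s and the mean distance from the arena center
≈ 25 cm — the behavioral statistics the sessions are meant to emulate.
The velocity noise amplitude is derived from `mean_speed` via the
stationary Rayleigh speed distribution (σ_component = mean/√(π/2)).

**Spiking.** Units carry Gaussian tuning: λ(t) = baseline +
Σ_f peak_f · exp(−‖pos(t) − center_f(t)‖² / 2σ_f²). Spikes are drawn by
thinning a homogeneous Poisson process at the ceiling baseline + Σ peaks
— exact, with no discretization bias beyond linear interpolation of the
25-Hz trace. Field centers translate linearly at `drift_rate` (cm per
15 min) in a per-session random direction; drift is the generative
mechanism for within-session instability.

**Genotype profiles.** Tuning parameters are drawn per cell from
clipped normal distributions:

| parameter | WT-like | KO-like |
|---|---|---|
| field σ (cm) | 6 ± 1 [4, 9] | 9 ± 1.5 [6, 14] |
| peak rate (Hz) | 12 ± 3 [6, 20] | 7 ± 2 [3, 12] |
| baseline (Hz) | 0.4 ± 0.15 [0.05, 1] | 1.0 ± 0.3 [0.2, 2] |
| drift (cm/15 min) | 1 ± 0.5 [0, 2.5] | 6 ± 2 [2, 12] |

Both profiles draw 1 field with probability 0.8 and 2 with 0.2. The
KO-like profile thus has broader fields, lower peak-to-baseline
contrast, and faster drift — the three generative knobs behind larger
field areas, lower specificity ratios, and lower split-half stability
downstream. The cohort default is 3 animals × 20 cells per profile
across the 2-day × 2-session plan, a size at which the genotype effects
are comfortably resolvable while a full 10-seed replication of the
analysis stays cheap.

**Probe session.** Cues are removed in session 4; `remap_on_probe`
(default 0.25) is the fraction of units whose field centers are redrawn
there. Real recordings report no quantitative remapping measure for the
probe manipulation, so this fraction is a modeling choice, not an
empirical claim; set it to 0 for a cue-insensitive cohort or 1 for full
remapping.

**What the simulation does not emulate.** Tracking dropouts and jitter,
theta modulation and phase precession, bursting and refractoriness
(spiking is Poisson), over-dispersed rate variability, experience-
dependent field sharpening, and any coupling between behavior and
firing beyond position. Passing tests therefore validate the analysis
chain and the direction of the genotype contrasts under the stated
generative model — they do not certify effect sizes on real data, and
simulated correlations run higher than published ones because the only
noise sources are Poisson spiking and finite sampling.

## Numerical notes and edge cases

- All randomness flows through `numpy.random.default_rng` seeds;
  identical seeds give bit-identical traces, spike trains and cohorts.
- Zero-rate maps yield no fields (not an error); silent units produce
  missing (NaN) metrics that the statistics layer drops and counts.
- Correlations with fewer than 20 shared valid bins, or with a constant
  map on the shared set, are missing rather than spuriously ±1.
- Wall reflection is iterated for the rare multi-crossing step and
  nudges an exactly-on-wall landing inward, keeping every sample
  strictly inside the arena for any seed.
- The exact Mann-Whitney p uses the min-U permutation distribution,
  which is inherently two-tailed (both directions shrink the minimum).
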