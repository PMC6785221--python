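# Methods

`hemicycle` analyzes bilateral motor-cortex population activity recorded
while a subject cycles a hand pedal with one arm at a time. The package
implements the full analysis chain — trial alignment, single-unit
lateralization statistics, cross-hemisphere comparison, subspace
variance-capture, trajectory tangling, and reduced-rank EMG decoding —
together with a synthetic-session generator that carries full ground
truth, so every stage has a recovery test that does not depend on access
to real recordings.

## Task structure and terminology

Eight unimanual conditions: performing arm (left/right) × cycling
direction (forward/backward) × starting pedal position (top/bottom).
Trials last seven cycles at roughly 2 cycles/s. Pedal angle is expressed
in cycles with 0 at the top of the cycle; vertical hand position is
cos(2π·angle); forward cycling increases the angle. For a neuron, the
*driven* arm is contralateral to its hemisphere; the *driving cortex* for
a condition is the hemisphere contralateral to the performing arm.

## Synthetic sessions

The generator produces what the analyses assume real sessions look like,
plus the internals needed for recovery tests.

**Latent signals.** Each (arm × direction) pair receives a set of
`latent_dim_per_arm` rhythmic latents, built as a random orthogonal mixing
of the quadrature pairs at the cycle fundamental and its first harmonic:

    z(θ) = Q [cos 2πθ, sin 2πθ, h·cos 4πθ, h·sin 4πθ]ᵀ,

where θ is absolute pedal angle (cycles) and h = `harmonic_weight`. The
orthogonal mixer makes the latent set's temporal spectrum exactly
(1, 1, h, h)/√2 — two strong directions and two weak ones — rather than
letting independently drawn phases collapse some directions to near-zero
power for unlucky seeds (degenerate weak directions make rank-selecting
linear decoders put enormous weight on them, which is an artifact of the
simulation, not a property of the analyses). Because latents are
functions of absolute pedal angle and the mixer is shared across start
positions, top-start and bottom-start conditions of the same arm and
direction produce the same response pattern up to a half-cycle phase
shift — the structure the start-position control correlation relies on.

**Arm subspaces.** The left-arm and right-arm latents enter the
population through two orthonormal bases over the unified two-hemisphere
population, constructed so that the cosine of *every* principal angle
between them equals `subspace_overlap` (0 → orthogonal, 1 → identical).

**Units.** Unit *i*'s intensity when arm *a* performs condition *c* is

    λᵢ(t) = max(0, baseline_rate + rate_gain · g·(1 + speed_coupling·s̃) ·
                   √N · aᵢ(a) · (B_a z_c(θ(t)))ᵢ · env(t)),

with aᵢ(driven) ~ U(0.2, 1) and aᵢ(non-driven) = (1 − lateralization) ×
an independent U(0.2, 1) draw: every unit responds for both arms with a
random, configurable contralateral bias ("mixed lateralization"). env(t)
ramps the modulation on during movement. s̃ is the trial's standardized
non-performing-arm mean speed; `speed_coupling` = 0 makes firing
statistically independent of those wiggles (the null for the speed-split
control). Spikes are drawn from an inhomogeneous Poisson process on a
1 ms grid. Rectification at zero keeps intensities valid; at the default
baseline (30 spikes/s) clipping is rare.

**EMG.** Muscles of the performing arm read out that arm's latents:
rect(offset + w·z) · env + noise, re-rectified. Readout rows have norm
in [0.8, 1.4] (every recorded muscle is robustly modulated — weak EMG
recordings would not be kept) and offsets in [0.4, 0.9], so rectification
clips a substantial lower tail: muscle activity is a genuinely nonlinear,
nonnegative readout, which is what gives muscle trajectories their high
tangling, while remaining decodable by a linear map. Non-performing-arm
muscles are silent except for an optional end-of-movement bump
(`stopping_emg_amplitude`, default 10% of a typical offset) — its
temporal profile is a free parameter of the generator, not a fit to any
published curve — plus sensor noise.

**Kinematics.** Per-trial speed is drawn once per trial from a truncated
normal (`cycle_rate_mean` = 2.0, `cycle_rate_sd` = 0.12 cycles/s,
bounds ±3 SD); the performing pedal advances monotonically through
`n_cycles` = 7 cycles between two stationary holds. The non-performing
pedal wiggles smoothly within ±`nonperforming_jitter_amplitude`
(default 0.01 cycles) of the bottom position, with a per-trial random
amplitude so that median splits on its mean speed are meaningful.

**Determinism.** A single root seed spawns a child stream for every
stochastic sub-step (bases, gains, muscle weights, mixers, two per
trial), so identical configs give byte-identical sessions regardless of
evaluation order.

Defaults (60 units/hemisphere, 20 trials/condition, 6 muscles/arm) are a
typical single session; analyses whose expected effect sizes depend on
sampling noise (subspace capture, wrong-arm decoding, tangling
comparison) are validated at the study-scale population of 100
units/hemisphere and 40 trials/condition, matching the pooled populations
(>200 units) and per-condition trial counts (~29) of the recordings the
analyses were designed for.

## Preprocessing

Spike trains are convolved with a Gaussian kernel, SD 25 ms (the common
convention for a "25 ms Gaussian" in this literature), truncated at ±4 SD
and normalized to unit spike mass, on a 1 ms grid. Raw EMG voltage is
zero-phase 4th-order Butterworth high-pass filtered at 40 Hz, rectified,
and smoothed with the same Gaussian. (The synthetic generator emits EMG
directly as smoothed intensity, so in the synthetic pipeline this filter
is exercised by its own analytic tests rather than by generator output.)

**Two-step alignment.** Trials are first anchored at the completion of
the first half-cycle — implemented as the first crossing of 0.5 cycles of
*unsigned cumulative* pedal travel, which treats forward and backward
cycling identically and tolerates tiny non-monotonic jitter. Second,
each rate trace is re-expressed as a function of unsigned cumulative
angle over the middle six cycles (0.5 to 6.5 cycles of travel) and that
angle is mapped linearly onto a canonical 0–3000 ms grid at 500 ms per
cycle. Interpolation is piecewise-linear in both maps; rate *values* are
never altered, only their time base. After alignment the warped pedal's
vertical position matches the condition's canonical sinusoid to < 1e-3.
Alignment runs on the 1 ms grid; aligned traces are sampled at the 10 ms
analysis resolution (information-preserving under the 25 ms kernel, and
it keeps the O(T²) tangling analyses fast). Trials whose pedal does not
complete the middle six cycles are rejected by trial id.

Aligned trials of a condition are averaged pointwise (SEM across trials,
ddof = 1). Most analyses use the middle four cycles (2–5), i.e. the
canonical window [500, 2500) ms: steady-state cycling, away from start
and stop transients where non-performing-arm muscles can be weakly
active.

## Single-unit statistics

*Modulation* is the population (ddof = 0) standard deviation of a unit's
trial-averaged rate concatenated over the four conditions of one arm
(cycles 2–5) — the ddof choice is a documented convention; at ~800
samples the difference is negligible. The *arm preference index* is
(mod_driven − mod_non-driven)/(mod_driven + mod_non-driven) ∈ [−1, 1],
undefined (NaN, propagated) only when both modulations vanish.

*Response correlations* are Pearson correlations of per-condition
mean-centered concatenations. The across-arm correlation pairs each
driven-arm condition with the matching (direction, start) non-driven-arm
condition. The start-position control correlates the four top-start
conditions (cycles 2–5) against the four bottom-start conditions shifted
by half a cycle (cycles 1.5–4.5) so pedal phase matches. The *shuffle
null* for the mean across-arm correlation replaces each unit's driven and
non-driven responses with those of two independently drawn units (with
replacement), 1000 times; the observed mean is significant if it exceeds
95% of resamples.

*Pairwise structure*: per condition, the unit × unit Pearson correlation
matrix (zero-variance units dropped and logged); the *meta-correlation*
is the Pearson correlation, over all pairs × condition types, between a
pair's correlation under driven-arm and under non-driven-arm
performance, pooled across hemispheres at the session level.

*Speed-split control*: per unit × condition, trials are split at the
median non-performing-arm mean speed (ties to the "below" group, making
the split deterministic); the observed |mean-rate difference| at each
timepoint is compared with 1000 random splits of the same sizes, flagging
timepoints whose difference exceeds the 1 − α fraction of the null
(two-sided via the absolute difference; the analysis is deliberately
pointwise, with the aggregate flagged fraction compared to the nominal
rate rather than multiplicity-corrected). Conditions with fewer than 8
trials return no result.

*Fano factor*: spike counts in two 250 ms windows flanking the 3.5-cycle
crossing of **unwarped** trials (time-warping would distort count
statistics); one slope per dataset from an OLS regression (free
intercept; through-origin exposed as an option; unweighted, with
weighting left to the caller) of count variance on count mean across
units × conditions × windows. ~1 for Poisson-like firing.

*Required magnification*: the smallest k ≥ 1 such that the median muscle
arm-preference index, with non-driven modulation scaled by k, falls to a
target (e.g. the neural median). The median is monotonically
nonincreasing in k, so monotone bisection (after doubling an upper
bound) finds it; unreachable targets (all non-driven modulations zero)
raise.

## Population geometry

Rates are *soft-normalized*: FR / (range(FR) + c) with c = 5 on the
spikes/s scale, range taken across all times and conditions — this keeps
high-rate units from dominating PCA without magnifying near-silent ones.
EMG uses plain range normalization (c = 0) since its scale is arbitrary.

*Condition subspaces*: PCA (SVD) of the time × unit matrix of one
condition, centered by its own temporal mean. *Variance capture* of a
test condition is the cumulative sum of squared projections onto the
leading PCs divided by the test matrix's total centered sum of squares —
a cross-space-comparable fraction. Test matrices are centered by their
own temporal mean by default (`center="train"` is exposed; the choice
matters little here because per-condition means are similar after
soft-normalization, and using the test condition's own mean keeps the
capture statistic a property of its shape rather than its offset).

*Triplet sweep*: every condition serves once as the training condition;
its same-arm test shares arm and direction (opposite start), its
opposite-arm test is the identical condition with the other arm; the
summary reports mean ± SD of capture at 5 PCs over the eight triplets.
The *neuron-count sweep* repeats this on random unit subsets: small
populations bias capture estimates away from orthogonality, so the
opposite-arm estimate falls toward its asymptote as units are added.
*Contribution weights* are the |loadings| of the top 5 PCs of each
arm-subspace, grouped by hemisphere.

*Trajectory tangling*: Q(t) = max over all times t′ (pooled across the
condition set) of ‖ẋ(t) − ẋ(t′)‖² / (‖x(t) − x(t′)‖² + ε), on states
reduced to the top 8 PCs fit once per arm's four-condition set, with
ε = 10% of the total variance across those dimensions. Derivatives are
central differences (one-sided at window edges) on the uniform 10 ms
grid. The t′ = t term is included (its ratio is 0 and never attains the
max), avoiding a special case. Q is invariant to orthonormal rotations
and to uniform rescaling of state space (ε scales with the variance).
The vectorized implementation performs the same arithmetic as the O(T²)
double loop and matches it exactly. For the comparison figure-of-merit,
distributions are pooled across hemispheres into "driving cortex"
(contralateral arm performing) and "non-driving cortex" sets, and across
arms for the muscles.

## Decoding

Generalization is scored with the population variance explained,
R² = 1 − ‖Y − Ŷ‖²_F / ‖Y‖²_F, on per-condition-centered targets (the
zero prediction scores exactly 0; poor predictions can be negative).

*Muscle decoders*: rank-r PLS2 regression (scikit-learn's NIPALS
`PLSRegression`; the variant is recorded in each model's provenance)
from soft-normalized, per-condition-centered rates to range-normalized,
per-condition-centered EMG. Training uses the same-arm/same-direction
condition with the opposite start position; the rank (candidates
1..min(20, dims)) is chosen to maximize R² on one validation cycle —
cycle 2, the first middle cycle, of the test condition — and
generalization is reported on the remaining cycles. Prediction-time
centering uses the test condition's own temporal mean, since a
per-condition offset is not decodable by a linear map fit elsewhere;
this is recorded in the model provenance.

*Cross-hemisphere comparison*: principal-components regression — the
target population is regressed on the top-r PC projections of the source
population (r = 1..10), trained and tested on opposite-start conditions.
Self-prediction is leave-one-out: each target unit is predicted from the
top PCs of all *other* target units. The *hemisphere shuffle test*
compares the observed self-minus-cross R² gap (mean over the 8
conditions, at rank 10) with 100 random permutations of the hemisphere
labels; significance requires exceeding the 95th percentile. Controls:
reconstructing the source without its first PC (signal removal) and
halving PCs 1–2 while doubling PCs 3–4 (signal rescaling) both degrade
cross-prediction, confirming the test can detect missing or mismatched
signals.

*Wrong-arm generalization*: for each arm and direction, a decoder is
trained on the top-start performing condition ("train-performing"; the
"train-both" variant adds the other arm's top-start condition),
validated on cycle 2 of the bottom-start performing condition, and asked
to decode the remaining cycles of the bottom-start condition performed
by each arm. Reported: decoded and actual modulation (std over time) per
muscle × condition, decoded arm-preference indices, and |decoder weight|
distributions by hemisphere.

## What the generator does and does not emulate

It reproduces the statistical structure the analyses rely on: mixed
per-unit lateralization with arm-unrelated patterns, configurable
subspace overlap with exactly controlled principal angles, rhythmic
low-dimensional latents shared across start positions, Poisson
variability, lateralized nonlinear EMG, and a nearly stationary
non-performing arm whose wiggles can optionally couple to firing. It
does **not** emulate: non-Poisson spiking history (refractoriness,
bursting), recording artifacts or unit-isolation drift, heterogeneous
latent spectra beyond one fundamental + one harmonic, genuine
biomechanics linking EMG to pedal force, bimanual coordination, or
inter-areal dynamics. Passing recovery tests therefore demonstrates that
the *analysis chain* measures what it claims under the assumed structure
— not that real cortex has that structure.

## Numerical choices and degenerate inputs

Smoothing kernels are truncated at ±4 SD and unit-normalized on the
discrete grid. The alignment warp inverts a monotone cumulative-angle
curve by linear interpolation. Zero-variance responses yield NaN
correlations (propagated, never imputed) and are dropped from pairwise
matrices with a log entry. Soft normalization maps zero-range channels
to zero when c = 0. Tangling requires ≥ 2 time points per trajectory;
rank requests beyond min(time, units) are rejected; PLS rank candidates
beyond the data dimensions are trimmed with a warning. All stochastic
steps (generator, shuffles, permutations, subset draws) derive child
seeds from a named root seed.

## Known limitations

- The speed-split type-I rate is exact only under exchangeability, which
  the null generator satisfies; real sessions with drift would need a
  blocked permutation scheme.
- The hemisphere shuffle test permutes labels (fixed group sizes) rather
  than re-assigning them independently; with balanced populations the
  distinction is immaterial.
- Leave-one-out self-prediction refits a PCA per held-out unit, which is
  O(units) SVDs per condition; population sizes beyond ~10³ would want a
  rank-one downdate.
- The EMG preprocessing path (40 Hz high-pass on raw voltage) is tested
  on analytic signals only, because the generator emits intensities
  directly.
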