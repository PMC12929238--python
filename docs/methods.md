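# Methods

This note records the statistical model the package implements, the
conventions chosen where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Latency estimation

The analysis window runs from `roi_start_ms` to `roi_end_ms` relative to
the disambiguating cue, with `saccade_offset_ms` (default 200 ms) added to
*both* boundaries to allow for saccade programming and execution. Bins are
half-open `[start, start + width)` intervals; a sample exactly at the
window end is excluded, so the window span is an exact integer multiple of
the bin width. Looks to excluded areas (default: whitespace) are removed
before the per-trial target proportion is computed, and proportions ≥ 0.5
binarize to 1. A latency is always the *start* time of its qualifying bin.

Per-bin test on binarized trial data: an intercept-only logistic regression
pooled over all trials of all participants of a group in the bin. With
`s` successes of `n` this fit is available in closed form (intercept
`b = log(p̂/(1−p̂))`, Wald `SE = 1/√(n·p̂·(1−p̂))`), which makes the per-bin
test deterministic and fast enough to run billions of times. The model is a
fixed-effect pooled fit, not a mixed model with participant intercepts;
cross-participant variability enters the inference through the resampling
procedures, not through the per-bin model. Under complete separation
(`s = 0` or `s = n`) the Wald test collapses, so those bins fall back to an
exact two-sided binomial test against 0.5 (`p = min(1, 2·0.5ⁿ)`), with the
estimate reported as ±∞ purely as a sign carrier. Significance is defined
as two-sided `p < α` *and* a positive estimate, which encodes
"significantly above chance" without choosing a one-sided α.

Per-bin test on participant-averaged proportion data: a one-sample t-test
of the relative proportion `competitor/(competitor + unrelated)` against
0.5. Participants whose competitor and unrelated proportions are both zero
in a bin have an undefined ratio and drop out of that bin only.
Zero-variance bins are degenerate and never significant. The effect-size
threshold on this path is a raw proportion difference (default 0.03,
roughly a 57% relative proportion).

Latency measures: `consecutive` (first of k = 5 consecutive significant
bins), `consecutive_threshold` (every bin of the run must additionally
exceed the effect-size threshold — the joint per-bin reading of the
criterion), `holm` (first Holm–Bonferroni-rejected bin with a positive
estimate, family = all bins of the window), and `holm_threshold`. Missing
bins count as not significant. When no bin qualifies the latency is
**censored at the window end** rather than dropped; this keeps every
bootstrap/permutation distribution at its nominal length, and the censored
fraction is reported alongside every distribution and aggregate rather
than silently absorbed.

## Resampling

The exchangeable unit is the participant. The by-participant bootstrap
redraws n participants per group with replacement (within condition strata
when requested, preserving per-condition counts); clones are relabeled so
duplicated participants weight pooled counts once per draw. The permutation
test reassigns whole participants to groups of the original sizes; the
p-value is the plain proportion `#{|null| ≥ |observed|}/P` with no +1
smoothing, so p lies on the grid {0, 1/P, …, 1} and the test is slightly
conservative.

The stratified bootstrap keeps every participant and redraws trial values
with replacement within each (group, participant, bin) stratum. For
binarized values, drawing m values with replacement from a stratum holding
s ones is distributionally identical to drawing the new success count from
Binomial(m, s/m); the implementation uses that equivalence, preserving
stratum sizes exactly. This scheme is implemented to be measured, not
recommended: because every resample contains the same participants, it
understates between-participant variability, and the package's own
simulations show its percentile-CI false-positive rate exceeding the
by-participant scheme's under 200-ms per-participant timing noise.

Bootstrap intervals: percentile (linear-interpolation empirical quantiles),
normal (`observed − bias ± z·sd`, bias = bootstrap mean − observed),
empirical/basic (`2·observed − q`), BC (`z₀ = Φ⁻¹(#{boot < observed}/B)`,
ties with the observed value excluded; z₀ clamped to ±Φ⁻¹(1/(B+1)) and
flagged when the count is 0 or B), and BCa. The "accelerated
bias-corrected" interval is implemented as standard jackknife BCa with
leave-one-*participant*-out acceleration `a = Σd³/(6(Σd²)^{3/2})`; the
approximate-bootstrap-confidence variant is not implemented, and the z₀/a
diagnostics are logged on every result. A bootstrap distribution with zero
range short-circuits every method to the zero-width interval at that value.
Wilson score intervals (via statsmodels) summarise all Monte Carlo
proportion estimates.

## Monte Carlo engine

Cells are the Cartesian product of group sizes × true shifts ×
per-participant noise SDs. Each simulation: assemble two groups, add the
cell's shift to every time stamp of the "shifted" group, optionally add one
Normal(0, sd) offset per participant to all of that participant's samples,
bin, estimate all four measures, then run the requested procedures.
Child RNGs derive from `(master_seed, cell index, simulation index)` via
`SeedSequence`, so identical plans reproduce byte-identical records in any
execution order.

Seed data can be (a) a `SyntheticSpec` — each simulation generates 2n fresh
participants from the spec with its group shift forced to 0, since the
generator supplies i.i.d. participants directly and a finite-pool
subsampling step would only add an extraneous dependence between
simulations; or (b) a real gaze or proportion table — 2n participants are
drawn without replacement (with replacement on request, for pools smaller
than 2n), balanced across conditions when requested, and relabeled
per-group so cross-group duplicates remain distinct units.

Power is the proportion of simulations whose CI lower bound exceeds 0 (or
permutation p < α with a positive observed difference); Type I error is the
proportion of CIs excluding 0 (either side) at shift 0, or p < α. Coverage
is the proportion of CIs containing the true shift. Because a rigid time
shift translates the latency-difference bootstrap distribution without
changing its shape, shift-0 records can be re-scored at any hypothetical
shift by translating the stored CI bounds (`pooled_shift_estimates`); the
re-scoring rule is "translated interval excludes 0", which at shift 0
reproduces the directly estimated two-sided Type I error exactly.

## Synthetic generator

Each participant's onset is `tau_base + delta_group + Normal(0, σ_subj)`;
trials jitter around it with SD `σ_trial`. Within a trial, gaze follows a
two-state persistent chain: with probability ρ a sample repeats the
previous state, otherwise it redraws from the marginal target probability —
`p_pre` (default 0.5) before the trial's onset, a linear ramp to `p_max`
over `ramp_ms` after it, and in competitor-transient mode a decay back
after `effect_duration_ms`. Whitespace looks replace the AOI label with
probability `p_whitespace`. Sampling is fixed-rate (default 120 Hz) or
webcam-like with lognormal inter-sample gaps (strictly positive,
right-skewed) at a specified mean rate. Defaults — 24 participants/group,
24 trials, onset 600 ms, σ_subj 60 ms, σ_trial 50 ms, p_max 0.95, ramp
200 ms, ρ 0.9, 5% whitespace — describe a clean infrared sentence-processing
experiment with a salient lexical cue and modest between-participant
variability.

The persistence parameter matters more than it looks: real 50-ms bins
usually contain a single fixation, so binarized trial×bin values are
Bernoulli at the marginal probability. With *independent* samples (ρ = 0)
and an even number of samples per bin, the "proportion ≥ 0.5 → 1" rule
inflates pre-onset binarized values above chance (ties resolve upward:
~0.66 at 6 samples and p = 0.5), which with enough trials makes pre-onset
bins genuinely significant and pulls the consecutive-bins onset early. The
default ρ = 0.9 keeps this artifact small, and tie-free checks use an odd
per-bin sample count (100 Hz → 5 samples per 50-ms bin). This is a real
property of the binarization rule, not a bug in the generator.

The proportion-table generator draws, per participant × bin, `n_trials`
independent multinomial AOI samples over (target, competitor, two unrelated)
with a trapezoidal competitor advantage (peak `comp_effect_size`, default
0.10) and a late target rise to `p_max`; condition labels scale the
competitor effect with evenly spaced multipliers, emulating
between-condition effect-size differences in preview designs.

What the generator does *not* emulate: saccade kinematics and fixation
durations (persistence is per-sample, not per-fixation, so webcam-mode
autocorrelation decays per sample regardless of gap length), item-level
crossed random effects, drift or calibration loss over a session, and
blink/track-loss structure. Passing tests therefore demonstrate that the
procedures behave correctly for data with participant-level onset
variability and within-trial autocorrelation — not that any particular
real dataset satisfies those assumptions.

## Problem sizes in the checked quantities

The distributional checks run at desk scale, chosen to keep Monte Carlo
error well inside the asserted margins: the null-calibration check uses
300 simulations × 200 permutations at n = 24/group (binomial SE ≈ 1.3
percentage points at the 5% level); parameter recovery uses 100 simulations
× 100 bootstrap resamples against a ±50 ms (one bin) margin; the
bootstrap-scheme comparison uses 200 simulations × 200 resamples per scheme
at n = 12/group with 200-ms noise, where the two schemes' false-positive
rates differ by a factor of several. Full-scale grids (thousands of
simulations × 2000 resamples) run through the same `simulate` entry point.
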