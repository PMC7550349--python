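# Methods

This note documents the models, numerical choices and limitations behind
`oflphys`. The package simulates and analyzes a two-phase observational
fear learning (OFL) experiment: an observational phase in which the
observer watches a demonstrator undergo differential conditioning, and a
direct-expression (DE) phase in which the observer faces the conditioned
stimuli themselves, with no shocks.

## Experimental design generation

The OFL phase has 24 CS+ and 24 CS− trials (12 CS+ reinforced), the DE
phase 12 + 12 with no US. CS order is drawn sequentially: at each position
the next stimulus type is sampled uniformly among the types that still
admit a valid completion (counts exact, no run of more than
`max_run_length = 2` identical stimuli), checked by a memoized recursion.
This samples the constraint set without rejection; it is not exactly
uniform over all valid sequences, which is irrelevant here because only the
constraints are specified. Reinforcement picks `round(ratio · n_CS+)`
trials (banker's rounding, so the behavior is defined for odd counts) and
always includes the first and last CS+. The US is modeled as a pulse train
(5 × 1 ms pulses, 200 ms inter-pulse latency → 0.8 s span) starting 7.5 s
after CS onset. CS presentations last 9 s; intertrial fixation intervals
are uniform on [10, 15] s; each phase opens with one lead-in fixation
interval so that every trial has a 2 s pre-stimulus baseline.

Startle probes cover half of the CS presentations (onsets drawn from
{6.0, 6.5, 7.0} s after CS onset) and a quarter of the ITIs (onsets uniform
on [2.0, 4.5] s after fixation onset, which the ≥ 10 s ITI keeps clear of
the next CS). Probe placement is *balanced by design*: equally many CS+
and CS− trials are probed, probed CS+ trials are split evenly between
reinforced and unreinforced trials, and ITI probes are balanced between
the intervals following probe-free reinforced and unreinforced CS+ trials.
The balancing exists because US-response scoring discards probe-
contaminated trials; without it the scoreable US and no-US trial counts
would differ at random. Whether the original counterbalanced sequences
did this is unknowable from the task description; we document our
stratification rather than guess.

All generated event times are quantized to 1 ms and all intervals are
half-open `[onset, onset + duration)`; times are seconds from phase start.

## Synthetic signal model

**EDA** (μS, 2 kHz): tonic level (5 μS) + linear drift (0.05 μS/min) +
Gaussian noise (sd 0.01 μS) + event-locked responses. Each response is a
peak-normalized biexponential kernel `h(t) ∝ e^(−t/3.0) − e^(−t/0.75)`
placed 1.5 s after its triggering event, so the kernel peak (≈ 1.39 s
later) stays inside the 0–6 s scoring window. Per-event amplitudes are
lognormal around the condition mean with CV 0.4 (SCR amplitudes are
non-negative and right-skewed) and are zeroed with probability 0.1;
US-locked responses always fire. Condition means encode the study
conditions: US responses 0.8 μS in every observer; DE responses 0.30 μS
(CS+) vs 0.18 μS (CS−) in aware observers and 0.18 μS for both in unaware
observers; observational-phase CS responses 0.15 μS. On reinforced trials
an additional US-sized response is placed at CS onset as well as at US
onset, representing the observer's reaction to watching the shock; this is
what CS-anchored scoring of the observational US picks up (see below).
The demonstrator-reaction latency has no published distribution; the
single fixed SCR latency doubles for it and is a documented free choice.

**EMG** (mV, 2 kHz): baseline Gaussian noise (sd 0.01 mV) plus one burst
per startle probe: white noise band-limited to 30–300 Hz (inside the
scorer's 28–500 Hz passband, matching an orbicularis-oculi spectrum),
Hann-windowed over 100 ms, starting 35 ms after probe onset. Each burst is
normalized so that the peak of its rectified-and-smoothed envelope equals
the intended gain — the startle scorer therefore measures exactly the
injected quantity, which makes amplitude bookkeeping testable. Gains:
0.10 mV in the observational phase, 0.14 mV in DE, multiplied in aware
observers' DE trials by 1.25 (CS+) or 1.15 (CS−) versus 1.0 (fixation),
with lognormal (CV 0.4) trial-to-trial variability. Habituation-phase
probes are not rendered.

**Questionnaire**: aware observers produce a correct, consistent answer
set (forced choice CS+, plus rule report and/or uniquely highest
percentage rating for CS+); unaware observers are drawn from incorrect or
inconsistent patterns (wrong forced choice; correct forced choice with
contradictory rule and ratings; tied ratings). Likert ratings are clipped
rounded normals matched to the target medians/IQRs
({6,6,8,4,7} / {2,3,2,4,2}).

What the generator does **not** emulate: probe-evoked SCRs, habituation,
respiration/motion artifacts, electrode drops, or any demonstrator
individuality. Passing tests therefore demonstrate that the scoring and
inference chain recovers known injected structure — not that it is robust
to every artifact of real recordings.

## EDA decomposition

Default method `convex_sparse`: the decimated signal (8 Hz; SCRs have
sub-hertz bandwidth) is modeled as `y = B c + K d + ε` with `B` a
piecewise-linear tonic basis (knots every 10 s), `K` convolution with the
biexponential kernel, and `d ≥ 0` a sparse driver. The driver solves
`min ½‖K d − r‖² + λ‖d‖₁, d ≥ 0` by FISTA (power-iteration Lipschitz
estimate, momentum restarts unnecessary at this conditioning, convergence
checked every 25 iterations, cap 300). The tonic coefficients are
initialized from a running 10th-percentile of the signal (a robust skin
conductance level estimate) and refit by sparse-Cholesky least squares
after each driver solve; two alternations suffice since both subproblems
are convex and well conditioned. λ defaults to `2·10⁻³ · sd(residual) ·
Σk`; small enough that recovered response amplitudes stay within a few
percent of injected values (the L1 shrinkage bias is ≪ the 0.2 μS floor),
large enough to keep the driver off the baseline. `highpass_baseline` is
a cheaper documented approximation (20 s running median as tonic,
non-negative remainder as phasic). The full-rate API linearly upsamples
both components back to the recording rate; the cohort pipeline scores on
the 8 Hz grid directly, where the window extrema agree with the full-rate
values to a fraction of a percent.

## SCR scoring

Amplitude = max of the phasic component over `[onset, onset + 6 s)` minus
its mean over `[onset − 2 s, onset)`; both windows half-open in samples.
The baseline is taken on the phasic component (the subtraction guards
against spontaneous fluctuations immediately before the stimulus).
Amplitudes below 0.2 μS (or negative) are no-responses (0). Responses to
the observational US are scored only on CS+ trials free of probes both
during the CS and in the following ITI — a probe response would bleed into
the US window — and unreinforced CS+ trials are scored identically as the
no-US control. Scoring is anchored at CS onset by default (the condition
labels of the published figure suggest CS-anchoring); `us_anchor="us"`
switches to US-onset anchoring, which the phrase "identical time window as
when the stimulus was present" can also be read to mean. Normalization is
`ln(1 + SCR/SCRmax)` (natural log — the base only rescales, every contrast
is invariant), with SCRmax the subject's largest raw response over **all**
scored trials. Condition means include zeros. Subjects with fewer than 5
non-zero DE responses are excluded ("less than 5": exactly 5 is retained).

## FPS scoring

Band-pass 28–500 Hz, 4th-order Butterworth response applied
forward-backward: zero phase preserves burst latency relative to the
scoring windows at the cost of an effectively squared magnitude response
(8 poles) — documented as the package's choice since causal filtering
would shift the 20–120 ms window. Rectification is the absolute value;
smoothing is a 40 Hz low-pass Hamming-window FIR (odd length ≈ 0.2 s,
> 50 dB stopband) applied centered, hence delay-free. Score = window peak
(20–120 ms) minus baseline mean (−100–0 ms), floored at zero. For cohort
runs the filter chain evaluates padded 0.5 s windows around each probe
(batched), which matches full-trace filtering to transient precision and
is an order of magnitude faster; the equivalence is tested.

T-scores (`50 + 10·(x − mean)/sd`, sd with n−1 — group contrasts are
invariant to the n/n−1 choice) are computed over **all** of a subject's
probed trials pooled across both phases, zeros included. Pooling across
phases is the critical interpretive choice: a per-phase reference would
erase the DE > OFL phase effect by construction. Habituation probes are
excluded from the reference set (none are rendered). Exclusions: 5 or
fewer non-zero responses over the whole experiment ("5 or less": exactly
6 is retained), or an overall-noisy recording, operationalized (the
original criterion was visual inspection) as baseline-window RMS exceeding
5× the cohort median in more than 25 % of trials.

## Awareness classification and ratings

Aware ⇔ forced choice = CS+ AND (rule reported for CS+ OR CS+ holds the
*uniquely* highest shock-probability rating) — "assigned highest" is read
as requiring a unique maximum, so ties classify unaware. Missing ratings
with no rule report classify unaware with basis "none" and a logged
warning. Likert summaries use linearly interpolated quartiles (the
convention is otherwise unstated) and Kruskal–Wallis (tie-corrected H,
chi-square p; all-identical input returns H = 0, p = 1).

## Group statistics

Paired *t* (two-tailed; Cohen's d = mean difference / sd of differences;
identical samples return t = 0, p = 1 rather than erroring, but a constant
non-zero difference — true zero variance with an effect — errors).
Repeated-measures and split-plot (mixed) ANOVAs are delegated to pingouin
with Type III sums of squares and partial η² = SS_eff/(SS_eff+SS_err);
for 2-level within factors sphericity correction is the identity and is
not applied, for 3-level factors the Greenhouse–Geisser ε and corrected p
are attached alongside the uncorrected integer degrees of freedom.
Between-group Cohen's d uses the pooled sd without small-sample
correction. Bonferroni post-hocs multiply each p by the number of
contrasts (capped at 1); confidence intervals stay at the uncorrected 95 %
level on the raw mean-difference scale. Constant-input designs report
F = 0, p = 1 (a degenerate case the underlying library leaves undefined).

## Problem sizes used by the test suite

The replicate-cohort recovery suite runs 20 replicates of 48 aware + 24
unaware observers through the full pipeline (simulate → decompose → score
→ classify → analyze) and requires each injected direction (SCR CS+ > CS−
in aware observers; startle DE > OFL; CS+ and CS− > fixation in aware
observers) to reach p < 0.05 in ≥ 95 % of replicates, and the unaware SCR
differential to stay at nominal false-positive rates. These group sizes
put the weakest injected contrast (CS− vs fixation, subject-level
d ≈ 0.7) at essentially certain per-replicate detection, so the 95 %
criterion tests the pipeline rather than sampling luck; smaller,
study-sized groups (14/21) would turn the same checks into coin flips for
that contrast. Type-I calibration of the mixed-ANOVA interaction uses
2,000 null simulations at the study's 14/21 split. Monte-Carlo module
checks (e.g. aware-subject CS differentials after scoring) use 40–100
seeded subjects with detection thresholds set so that their flake
probability is ≪ 10⁻³ at the measured effect sizes.

## Known limitations

* The convex decomposition is our FISTA implementation of the
  sparse-deconvolution program, not a wrapper of an external cvxEDA
  package; hyperparameters (λ, knot spacing, decimation rate) are package
  defaults, not fitted to real data.
* The synthetic US response is injected at both CS onset and US onset so
  that either scoring anchor yields a US ≫ no-US contrast; real timing of
  demonstrator reactions will differ.
* Statistical results on synthetic cohorts are much stronger than typical
  human data (no artifacts, known effect structure); effect sizes printed
  by the worked example should not be read as empirical predictions.
* The events/recording formats are plain TSV designed for diffability,
  not for acquisition-vendor compatibility.
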