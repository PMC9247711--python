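# Methods

This note documents the models and procedures `axovis` implements, the
assumptions behind the synthetic session generator, and the numerical
choices made where the procedure leaves freedom.

## Data model and alignment conventions

All times are seconds from session start. Every analysis window is
half-open, `[t0, t1)`, so an event sitting exactly on a boundary is counted
once. Events are mapped to frames causally ("last frame at or before the
event"), the appropriate alignment for a slow calcium indicator whose
response follows its cause. Missing values in the CSV tables are empty
fields; the trial table enforces that a reward time exists exactly on
correct go trials and an airpuff time exactly on incorrect no-go trials.

## ΔF/F baseline

`compute_dff` forms `F0` as the 5th percentile of the smoothed raw trace in
a 20 s window centered on each sample and returns `(F − F0)/F0`. Choices:

- **Smoothing** before the percentile is a 1 s centered boxcar, truncated at
  the session edges (`smooth_s`, set to 0 to disable). Mild smoothing keeps
  single aberrant samples from defining the baseline.
- **Window truncation**: the window shrinks near the session edges rather
  than padding, so the first and last samples use one-sided statistics.
- **Percentile convention** is numpy's linear interpolation; the window is
  `round(20 s / dt)//2` frames on each side of the sample.
- **Positivity floor**: `F0` is clamped at `1e-3 ×` the trace median and the
  ROI flagged, because a baseline that reaches zero (e.g. a detector
  dropout) would otherwise blow up the division. When the floor is never
  hit, ΔF/F is exactly invariant to multiplicative gain on `F`.

Merging treats "same axon" as an equivalence relation: boutons are grouped
by connected components of the graph with edges where Pearson r > 0.7
(strict), computed on ΔF/F rather than raw F so shared slow baselines do not
create spurious edges. Groups are replaced by the average weighted with each
member's ROI pixel count. Zero-variance traces have undefined correlations
and remain flagged singletons.

## Task statistics

The within-trial period runs from the trial-start tone to stimulus offset;
the inter-trial reference is the final 2 s of the quiescent period
immediately before the tone, and a trial is excluded when any lick falls in
that reference window ("properly executed" quiescence operationalized as
lick-free). The classification test is a two-sided paired t-test at
p < 0.01; the TMI is computed from the trial-mean activities. With
nonnegative activity TMI lies in [−1, 1]; negative ΔF/F can push it outside
that range, in which case the value is reported as-is and flagged rather
than clipped. Event responses compare mean ΔF/F in `[t − 0.5 s, t)` against
`[t, t + 1 s)` with a one-sided (increase) paired t-test and BH correction
across boutons within each event type, flagged at adjusted p < 0.05.

## Accuracy association

`d′` uses the inverse normal CDF of hit and false-alarm rates. Rates of 0
or 1 make the quantile infinite, so the default policy replaces them by
`1/(2n)` and `1 − 1/(2n)` with `n` the relevant trial count; a log-linear
policy (`(k + 0.5)/(n + 1)`) and an uncorrected variant (returns ±inf with
a warning) are available. The sliding series uses 20-trial windows stepped
by one trial, dropping windows that lack either trial type.

The correctness model is ordinary least squares of per-trial activity on
`[1, correct, trial_type, correct × trial_type]` with treatment coding
(correct = 1, go = 1), coefficient t-tests, and BH correction across
boutons per coefficient. This is the Gaussian identity-link special case of
a GLM fit, which is what a default GLM fit reduces to. A rank-deficient
design (e.g. correctness identical to trial type) skips all boutons with a
recorded reason; the `previous_correct` variant lags correctness by one
trial and drops the first trial.

The d′-vs-activity regression fits, per session, a straight line predicting
windowed d′ from windowed population ΔF/F and tests the per-session slopes
against zero with a two-sided one-sample t-test. Regressing d′ on activity
(rather than the reverse) makes a session with constant population activity
the degenerate case, which is excluded with a log entry.

## Licking and reward

Lick rate is the lick count in a centered 1 s window per frame, kept
nonnegative (any sign flip in displays is cosmetic). The permutation test
circularly shifts the lick-rate trace 1,000 times by a whole-frame offset
drawn uniformly from `[min_shift, T − min_shift]` with `min_shift` = 10 s
(both shift directions fold onto one circular index); a bouton is
significant when its observed correlation exceeds the 95th percentile of
its own null, the one-sided criterion matching the exceedance rule. The
reported `p_perm` is the add-one permutation p-value, bounded below by
`1/(n_perm + 1)`.

Rewarded licking periods run from reward delivery to stimulus offset of the
go trial (the reward window closes at stimulus offset); unrewarded licking
periods are the first 2 s of the go stimulus, where responses do not count,
and only periods actually containing a lick contribute — the comparison is
between licking states, not between arbitrary epochs. Lick bouts are ≥3
licks within 0.5 s of the first, preceded by ≥1 s of silence; bout-matched
comparisons use only the first three licks of each bout so rewarded bouts'
greater duration cannot confound the contrast. RTI is computed per bouton
from rewarded-period means on contralateral vs ipsilateral trials and
tested across the population with a two-sided one-sample t-test against 0.

## Tuning

Responses are mean ΔF/F over 1 s after each grating onset. The eight
stimulus "orientations" are treated as eight directions spanning 360°
(orientation = direction mod 180°), which is what makes DSI meaningful.
The tuning model is `R(θ) = offset + A1·G(θ − θp; σ) + A2·G(θ − θp − 180°;
σ)` with wrapped angular distance, a shared width, a common offset, and
`A1, A2 ≥ 0`; `θp` is fixed at the empirical argmax direction rather than
left free, since preference is defined empirically. The position dimension
is collapsed to each neuron's best position (largest overall mean) before
fitting. Fits use bounded nonlinear least squares on the per-direction
means (σ ∈ [1°, 180°]); OSI and DSI are evaluated from the fitted curve,
with `R_ortho` at 90° from preference. Responsiveness is a one-way ANOVA
across conditions at p < 0.05 (zero within-condition variance with
differing means counts as responsive; a completely flat neuron is
degenerate and not responsive). The activity split orders presentations by
the concurrent axon-population mean and assigns the upper half to "high"
(stable argsort, half sizes differ by at most one); neurons enter the
OSI/DSI Kruskal–Wallis comparison only when responsive and with r² > 0.3 in
both halves.

## Pupil geometry

The eyelid contour is built in a rotated frame whose abscissa is the
medial→lateral axis, making "a parabola through medial, apex, lateral"
well-posed for tilted eyes. Frames are invalidated — discarding all pupil
markers — when the medial marker is not medial of the lateral one (image
x-coordinate convention), when a lid apex falls outside the corner span or
on the chord (degenerate contour), or when both apices sit on the same side
of the chord. The interior test is strict, so boundary points count as
outside. The ellipse fit is a direct algebraic least-squares conic fit with
an ellipse constraint (closed-form and deterministic); a fit is attempted
only with ≥6 valid markers, "diameter" is the major-axis length, and
velocity is the frame-to-frame displacement of the fitted center divided by
the time step, missing across invalid frames.

## Synthetic sessions

The generator emulates the trained task: a 0.1 s tone, the grating 1 s
after tone onset lasting 4 s, reward available 2–4 s after go-stimulus
onset, a 500 ms airpuff plus 10 s timeout after false alarms, and 2–10 s
uniformly drawn quiescent periods. The agent hits with probability
`hit_rate` on go trials and false-alarms with probability `fa_rate` on
no-go trials (optionally following a slow bounded random walk to mimic
within-session accuracy drift); trained animals respond promptly once the
reward window opens, so the response latency is ~0.3 ± 0.15 s after window
opening. Rewarded licking is a rhythmic bout at 7 Hz lasting 1–2 s
(truncated at stimulus offset); unrewarded licking is sparse and short
(impulsive bouts at stimulus onset on 40% of trials, occasional
spontaneous licks outside trials). These defaults reproduce the contrasts
the analyses rely on — rewarded licking longer and more rhythmic (>6 Hz)
than unrewarded licking — without being calibrated to any particular
recording.

Bouton traces follow a linear-convolutional model: behavioral regressors
(per-frame lick counts, tone and reward impulses, stimulus/trial/correctness
boxes) scaled by coupling weights, plus Poisson shot-noise background
events, convolved with a difference-of-exponentials kernel (rise 0.2 s,
decay 1.5 s — a slow green-indicator stand-in that reproduces the temporal
blurring the analyses face), plus white Gaussian noise. The hemispheric
gain multiplies only the reward-coupled component on contralateral trials,
which gives the reward-targeting index the analytic target
`(g − 1)/(g + 1)`; each bouton's reward response also carries fractional
trial-to-trial jitter (a synaptic-variability stand-in, default SD 0.25).
Raw-fluorescence output embeds the signal multiplicatively on a per-ROI
offset, `F = F0·(1 + s)`, so the ΔF/F stage has real work to do.

Passive tuning sessions present 8 directions × positions in shuffled order
at 1 s spacing; soma responses are drawn from the ground-truth double
Gaussian as a box over the stimulus window (no indicator kernel on somas,
so condition means equal the generative curve exactly in the noiseless
case), while concurrent axon traces are slow shot-noise fluctuations whose
population mean defines the high/low modulator state; a soma's
`modulator_interaction` scales its preferred-direction amplitude on high
presentations. Pupil frames place the eight pupil markers on the true
ellipse at octagon angles with optional jitter, displace outliers and blink
frames far past the upper lid, and keep the four eyelid markers fixed.

What the generator does **not** emulate: pixel-level imaging (no movies, no
registration artifacts), neuropil contamination, nonlinear indicator
dynamics and saturation, orofacial movement confounds, eye images (only
landmark coordinates), or realistic inter-bouton correlation structure
beyond shared behavioral couplings. Passing recovery tests therefore shows
the statistics are implemented correctly and calibrated under the assumed
generative structure, not that real recordings satisfy that structure.

## Problem sizes and calibration experiments

The prepackaged calibration experiments (`axovis.experiments`) use a
~2,000 s session at 10 Hz with 400 uncoupled boutons and 1,000 circular
shifts for the permutation-test specificity (nominal 95%), and 5,000 null
boutons × 250 trials for the paired-test type-I error at p < 0.01 (nominal
0.01). Test-suite recovery experiments use sessions of 60–300 trials with
12–150 boutons and tuning experiments of 8 directions × 6 repeats, sizes at
which every check runs in seconds while the binomial confidence intervals
remain tight enough to be informative.

## Known limitations

- The permutation-test exceedance criterion is one-sided; boutons strongly
  *anti*-correlated with licking are not flagged.
- The correctness model assumes homoscedastic Gaussian residuals per
  bouton; heavy-tailed activity would call for a robust variant.
- Tuning fits have 4 free parameters against 8 direction means; with noisy
  flat cells the r² gate (> 0.3), not the fit itself, is what prevents
  overinterpretation.
- Bout labeling assigns "rewarded" by bout start time only; a bout
  straddling the end of a reward period keeps its label.
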