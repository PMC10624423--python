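# Methods

This note documents the statistical procedures `trialhist` implements, the
conventions and defaults it adopts where a choice had to be made, what the
synthetic-data generator does and does not emulate, and the known
limitations.

## Task and data model

Trials of a head-fixed go/no-go texture discrimination are described by a
table with one row per trial: a 1-based global `trial_index`, a
`session_id` (one session = one daily recording), the texture class
(`go`/`nogo`), the lick decision, and the outcome, which is a pure function
of texture × lick: Hit (go, lick), Miss (go, no lick), FA (nogo, lick),
CR (nogo, no lick).

Imaging data are event-aligned tensors of normalized fluorescence
(ΔF/F = F/F₀ − 1), trials × frames × channels at 20 Hz, with the time axis
in seconds relative to the moment the texture stops at the whiskers
(t = 0). Channels are either named cortical areas (here "BC", barrel
cortex, and "RL", rostrolateral association cortex) or pixels on an H × W
grid. Two canonical trial-time windows are used, both half-open on frame
timestamps: **pre** = [−1.0, −0.6) s (texture approaching, mostly before
first touch) and **stim** = [−0.2, 0.2) s (texture in touch). Endpoint
convention and the pre-window sign are configurable via `WindowDef`.

Baseline normalization ("frame-zero division") divides each trial and
channel by the mean of the 20 frames preceding the stimulus cue and
subtracts 1, so the baseline is ~0 and additive effects in ΔF/F units
compose linearly. Trials with non-positive baseline are flagged invalid
rather than silently dropped. When a calcium-insensitive control
wavelength is available, it is normalized the same way, resampled onto the
signal grid if acquired interleaved, and subtracted frame by frame — plain
subtraction without regression scaling, cancelling any additive
contamination (hemodynamic or photometric) common to both wavelengths.

## History pairing

Every trial is paired with its immediate predecessor *within the same
session*; pairs never cross the overnight boundary, since the inter-day
gap breaks the trial-to-trial continuity the history hypothesis concerns.
The main contrast is CR-Hit vs Hit-Hit (identical current trial, different
predecessor). A phase enters the modulation analyses only with ≥ 20 trials
of each pair type; sparser pairs (e.g. Miss-Hit) are excluded rather than
pooled.

## Learning curves and threshold

Sensitivity is d′ = Z(hit rate) − Z(FA rate) with Z the probit. Rates of
exactly 0 or 1 are clipped to 1/(2N) and 1 − 1/(2N) per bin (N = go or
no-go trials in that bin); the clipping rule is a convention, chosen to
keep the probit finite while letting d′ still reflect sample size. Curves
use non-overlapping 100-trial bins; a trailing partial bin is dropped;
bins lacking either trial class are flagged missing.

The curve is fitted with s(t) = a / (1 + exp(−(t − b)/c)) by bounded least
squares (a ∈ [0, 6] d′, b within the observed bin-center range, c > 0)
from an 8-point multi-start grid over (b, c) to avoid local minima. The
learning threshold is b, the half-amplitude (inflection) trial. A fitted
amplitude below 0.05 d′ marks the fit degenerate — b is then
unidentifiable and no threshold is returned. Phases are one session each:
naive = first session entirely before the threshold with ≥ 20 trials of
each main pair type, learning = session containing the threshold,
expert = last session (flagged if learning and expert coincide).

## History modulation and onset

The modulation index is Δ = mean(CR-Hit) − mean(Hit-Hit), per frame along
trial time, or per 100-trial bin along the learning dimension (stim-window
averaged activity, bins anchored at trial 1, the bin containing the
threshold defining relative trial 0). Significance uses a trial-shuffle
null: the pooled trials are randomly repartitioned into groups of the
original sizes (1000 iterations by default) and Δ recomputed each time;
the band is the per-frame (or per-bin) shuffle mean ± 2 SD. The onset is
the first point with Δ above the *upper* band — the hypothesis is an
activity increase on CR-preceded trials; a two-sided option exists.
Shuffles repartition within the analysed phase, ignoring session of
origin.

Two numerical choices matter here:

- **Persistence rule.** The composed scans (`trialtime_modulation`,
  `learning_modulation`) require the crossing to persist for 2 consecutive
  frames/bins by default (`detect_onset` itself defaults to a single
  crossing). With ~2–3% per-point band exceedance under the null and ~80
  frames per trace, a single-crossing scan would produce a false onset in
  most null traces. The generator's frame noise is iid, unlike the
  temporally smooth calcium signal, so a two-point persistence rule is the
  minimal smoothness assumption that keeps the per-trace false-onset rate
  near the single-test level (~5%) while leaving a genuine sustained onset
  untouched. Real sustained responses at 20 Hz span many frames, so the
  rule costs no sensitivity there either.
- **Shuffle RNG.** Permutations are drawn vectorised (argsort of a uniform
  matrix) from a single seeded generator in bounded batches; results are
  exactly reproducible given the seed and independent of batch size.

Across subjects, the learning-dimension onsets (absolute trial numbers)
are correlated with the learning thresholds by Spearman rank correlation;
subjects without a detected onset are excluded and counted, and the
correlation requires at least three detected onsets.

## Discrimination (ROC-AUC)

The AUC between two trial groups is P(a > b) + ½P(a = b) over all cross
pairs — the Mann–Whitney U statistic normalized by n_A·n_B, computed via
midranks (ties get half credit). Orientation is fixed and not rectified:
CR-Hit (history mode) or Hit (current mode) is the positive class, so
values below 0.5 are meaningful. Frame-wise traces use raw frames (no
smoothing); pixel maps use window-averaged values. Groups below 10 trials
per class are refused. Cohort comparisons use Wilcoxon signed-rank (Pratt
zero handling) between paired per-subject AUCs and against chance (0.5).

## Movement controls

Body movement per camera frame step is 1 − Pearson correlation between
consecutive frames' pixels within body ROIs (forelimbs, neck), averaged
across ROIs; steps with zero variance are undefined and excluded from
averages, not zero-filled. The whisker envelope is the sliding max − min
of the whisker angle over a 50 ms window (one imaging frame), centered,
and baseline-normalized by *subtraction* — angles can be near zero, so the
imaging division convention is not meaningful here. Video-rate traces
(30 Hz body, 50 Hz whisker) are linearly resampled onto the 20 Hz imaging
grid before window averaging. History comparisons use rank-sum within
subject and signed-rank across subjects; a missing modality is reported as
missing, never silently passed.

## Cohort statistics

The cohort stage compares stim-window BC activity in a subject × history
(2) × phase (3) repeated-measures two-way ANOVA with conventional
within-subject degrees of freedom; sphericity is not corrected and the
output says so. Post hoc history contrasts within each phase are
Tukey-adjusted. Missing cells abort the ANOVA (no imputation); constant
data are rejected as zero-variance. Cohort grand averages are recomputed
from the stored per-subject values, and a test asserts this consistency.
Re-running the pipeline with the same config and seed reproduces every
output byte for byte; outputs carry no timestamps.

## Synthetic-data generator

The generator is first-class, tested code: every analysis-recovery test
runs against data whose ground truth it records.

- **Stimulus sequence**: per-trial Bernoulli(p_go = 0.5) draws with
  rejection — a draw extending a same-texture run beyond `max_repeats`
  (default 3) is redrawn — which enforces the run constraint exactly.
- **Behavior**: the population d′ follows a/(1+exp(−(t−b)/c)); the target
  is split symmetrically about an unbiased criterion, hit rate = Φ(d′/2)
  and FA rate = Φ(−d′/2), and licks are independent Bernoulli draws.
  Defaults (a = 2.5 d′, b = 1000 trials, c = 150 trials, ~500 trials per
  session over 5 sessions) emulate the study conditions of mice learning
  within roughly a thousand trials over about a week.
- **Imaging**: single-trial responses use a half-cosine 200 ms ramp to a
  plateau spanning the target window — a convention; single-trial
  waveforms and noise statistics are not claims about real data. BC
  carries a stimulus response (5% ΔF/F on go trials; 40% of that on no-go
  trials, so the Hit-vs-CR "current" contrast exists); RL carries a small
  anticipatory pre-window response. The history effect (+2% ΔF/F by
  default) is added on CR-preceded trials from the learning-time onset
  trial onward (hard step; an optional linear ramp exists but is off, so
  onset-recovery tests stay sharp), in the stim window for BC and the pre
  window for RL. Per-frame iid Gaussian noise (σ = 5% ΔF/F) is added.
- **Contamination/control**: an optional slow per-trial trace (0.2 Hz
  sinusoid plus AR(1) drift) is added identically to the signal and the
  control channel, so control subtraction recovers the contamination-free
  signal exactly; RNG sub-streams are keyed per component so toggling
  contamination leaves all other draws unchanged.
- **Movement**: body metric and whisker angle are drawn from one
  distribution for all trials (a stim-locked bump and whisking sinusoids
  with random per-trial amplitude/frequency/phase), so any detected
  history difference in movement is a false positive by construction.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: temporally correlated (1/f, hemodynamic)
noise within trials, trial-to-trial response amplitude correlations, slow
drifts in behavior within a session, lick-latency structure, spatially
correlated pixel noise, and any biophysics of the calcium indicator. The
acceptance properties show the estimators recover what was injected under
the stated noise model, not that the biological effects exist.

## Problem sizes

The test suite and the acceptance script use desk-scale problem sizes
chosen to make the statistical properties measurable in seconds: cohorts
of 3–7 subjects, 600–3600 trials per subject, 80-frame trials, 1000
shuffle iterations, and 50–1000 replicate simulations per calibration
check. The cohort-scale quantities (onset medians, onset–threshold rho)
are qualitative mirrors of the study's seven-mouse dataset, not
re-derivations of its printed values, which would require the original
recordings.

## Known limitations

- No multiple-comparison correction across frames/bins beyond the
  persistence rule; the band is a pointwise 2 SD band.
- The RM-ANOVA reports uncorrected (sphericity-assumed) p-values.
- The sigmoid fit assumes a monotone learning curve; non-monotone
  performance (e.g. disengagement late in a session) can bias b.
- Learning-dimension bins mix trials across session boundaries by design
  (the learning axis is trial number, not day).
- The report layer emits both SEM and MAD alongside medians where a single
  dispersion convention is ambiguous.
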