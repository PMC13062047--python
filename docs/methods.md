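# Methods

## Scope and design

`somnotherm` quantifies three coupled phenotypes of sleep onset in mouse
polysomnography: the delta-power surge at the wake→NREM transition, the
coincident drop in core body temperature, and warmth-induced somnogenesis
(the increase in NREM time under a warm ambient environment).  Because the
kind of data it targets is rarely distributable, the package ships a
synthetic generator whose presets encode the wild-type and Dravet-model
phenotypes; every analysis stage is validated by parameter recovery against
that generator's ground truth, plus analytic and cross-implementation
oracles for the numerical components.

## Synthetic generator

### Vigilance-state process

States wake / NREM / REM evolve as an alternating-renewal (semi-Markov)
process on a 5-s epoch grid.  Bout lengths are exponential with per-state
means (default 150 s for wake and NREM, 30 s for REM), truncated below at
one epoch; the expected bout length in epochs is then
`1 / (1 − exp(−epoch/mean))`.  After each bout the next state is drawn from
an embedded entry matrix; REM is entered only from NREM with probability
0.05 (short recordings of juvenile mice reach NREM but essentially no REM,
so the default REM fraction is ~0.5 %).  Sessions start awake.

Stationary state occupancy is analytic: with embedded stationary
distribution π and mean bout lengths m, occupancy_i ∝ π_i·m_i.  The warmth
effect is implemented as a change of entry probabilities, not bout-length
scaling: in WARM blocks a fraction λ of every row's non-NREM entry mass is
moved onto NREM, with λ solved (Brent) so that NREM occupancy exceeds the
RT value by exactly `warm_nrem_boost`.  This keeps the configured boost
exact in expectation and testable against Monte-Carlo occupancy.

Defaults per preset: wake/NREM occupancy ≈ 0.50/0.50 at RT;
`warm_nrem_boost` = 0.15 for WT and DS_RESCUED, 0 for DS.  The boost value
is a modeling choice (the phenotype source reports a clear warm-block NREM
increase in responders without printing group means).

### Signals

ECoG/LFP = pink-noise background (1/f power, flattened below 0.5 Hz,
20 µV RMS) + a 0.5–4 Hz narrowband oscillator whose amplitude is 8 µV RMS
in wake and `nrem_delta_gain` × 8 µV in NREM (gain 3 for WT/DS_RESCUED;
1 for DS — the attenuated delta surge *is* the DS phenotype) + a 4–8 Hz
oscillator of 30 µV RMS in REM, sized so REM epochs satisfy the
theta/delta > 2.5 scoring criterion.  EMG = 20–100 Hz noise with per-state
RMS (wake 30, NREM 8, REM 4 µV).  State switches are cross-faded over
0.5 s.  The default sample rate is 250 Hz (configurable to 1 kHz); the
Nyquist frequency must exceed the 99 Hz analysis ceiling.

Interictal spikes are biphasic Gaussian-derivative pulses (60 ms support,
SD 8 ms, spectral peak ≈ 20 Hz) at Poisson times, peak amplitude 6× the
robust SD of the background, at 1/min for the DS and DS_RESCUED presets and
absent in WT.

### Temperature

A 1 Hz trace around the preset baseline (37.0 °C WT; 36.2 °C DS — the DS
offset of −0.8 °C is a free parameter standing in for a reduced baseline
whose magnitude is not published) with a slow sinusoidal drift (0.08 °C
amplitude, 40 min period, random phase) and white measurement noise
(SD 0.03 °C).  At each NREM onset, independently with probability
`temp_drop_prob` (0.65 WT / 0.21 DS), an exponential drop of 0.4 °C with
time constant 60 s is superimposed for the duration of the NREM bout and
recovers with time constant 120 s afterwards.  The drop magnitude and
kinetics are modeling choices within the 0.3–0.5 °C range typical of
published sleep-onset temperature drops in mice.

Drift and noise amplitudes were chosen so that, over the classifier's
windows, a genuine 0.4 °C drop is essentially always below the −0.1 °C
threshold while drift alone stays inside ±0.1 °C; with drops spaced by a
few hundred seconds the recovery transient of one drop does not contaminate
the baseline window of the next.  Closely consecutive drops can interact
(the second begins on a depressed baseline), which slightly biases Δ toward
zero; the noise-free exactness test therefore uses well-spaced cycles.

## Vigilance scoring

Per 5-s epoch: delta (0.5–4 Hz), theta (4–8 Hz) and total power of the
ECoG/LFP (Hann-windowed, mean-detrended periodogram of the epoch) and EMG
RMS.  The decision cascade — artifact → high EMG = wake → theta/delta > 2.5
with EMG at or below the median NREM EMG = REM → delta above threshold =
NREM → quiet wake — is deterministic given thresholds.

Thresholds are fitted per recording.  The EMG threshold is an Otsu
two-class split on log EMG RMS; when the maximal between-class variance is
flat across an empty valley the threshold is placed at the valley center.
The delta threshold is an Otsu split on log delta power of the low-EMG
epochs **with a unimodality guard**: when the two Otsu classes are
separated by fewer than 3 within-class SDs the distribution is treated as
single-mode and the threshold falls back below its 1st percentile.  The
guard matters twice: in DS-like recordings NREM carries no delta surge, so
low-EMG epochs cannot be split by delta power and scoring must ride on the
EMG criterion; and even in WT recordings whose low-EMG epochs are almost
all NREM, an unguarded Otsu split would bisect the NREM mode.  (The
separation statistic is ≈ 2.6 for a unimodal normal, > 4 for well-separated
modes.)

Artifact epochs are those whose peak ECoG amplitude exceeds 8 robust SDs of
the channel or whose total power strictly exceeds the 99.9th percentile
across epochs.  Wake/NREM alternation runs — consecutive wake/NREM runs of
at most 4 epochs (20 s, inclusive) containing at least one same-state
recurrence — are relabelled TRANSITION; the rule is idempotent.
`score_agreement` compares two scorings (ARTIFACT excluded from the
denominator), emulating the dual-human consensus step of visual scoring.

## Spectral estimation

Welch PSDs: Hann window, 50 % overlap, 5-s segments (0.2 Hz resolution;
a 30-s analysis window averages 11 overlapped segments), per-segment mean
removal, one-sided density scaling — the integral of density over frequency
equals the mean square of the input within ~2 % for stationary signals.
Band power sums density × bin width over bins whose **center** lies in the
closed band; consequently both edges of abutting bands count the shared
bin, and on the 0.2 Hz grid the delta-ratio bands 0.9–3.9 / 0.9–99 Hz have
effective edges 1.0–3.8 / 1.0–99.0 Hz.  Two delta conventions coexist
deliberately: 0.5–4 Hz for classification features and the virtual delta
channel, 0.9–3.9 over 0.9–99 Hz for the reported delta ratio; they are
never conflated.

## Transition-locked analysis

Eligible onsets need ≥ 120 s contiguous wake before (TRANSITION epochs
tolerated only in the final 20 s) and ≥ 90 s contiguous NREM after — the
minimum geometry that hosts the wake window [onset−120, onset−90) s and
NREM window [onset+60, onset+90) s.  When the wake window overlaps an
artifact epoch it slides earlier in 5-s steps by up to 30 s, else the event
is dropped (with a logged reason).  Temperature change: baseline = mean
over [onset−60, onset) s, post = mean over [onset+60, onset+180) s;
negative / unchanged / positive with an ε = 0.1 °C unchanged band.  The
windows and ε are this package's choices — the underlying protocol never
quantifies "unchanged" — and are configurable.  Raising ε can only move
events toward `unchanged`.  Per-subject averaging (bin-wise PSD mean, ratio
mean) precedes cross-subject averaging, so each animal contributes one
value.

## Statistics

The r×c exact test uses the Freeman–Halton probability-ordering criterion:
the two-sided p is the total multivariate-hypergeometric probability (fixed
margins) of all tables at most as probable as the observed one, by full
enumeration for grand totals ≤ 500 and by seeded Monte-Carlo permutation
sampling above that.  Ties are accepted within a 1e-10 relative tolerance.
Holm–Šidák follows the step-down formula
`adj(i) = max_{j≤i} (1 − (1 − p(j))^(m−j+1))` clipped at 1.  The two-way
ANOVA is deliberately delegated to statsmodels (OLS, Type II sums of
squares; the repeated-measures variant blocks on subject), as a standard
procedure outside the package's contribution.  The spike detector
band-passes 20–80 Hz, thresholds at 5 robust SDs, requires a biphasic
excursion (both polarities beyond threshold within ±40 ms, rejecting
one-sided noise exceedances) and merges events within a 200 ms refractory
period.

## Problem sizes and sampling error

The calibrated reproduction cohorts are 6 wild-type subjects × 2 h and
8 DS subjects × 100 min at room temperature, chosen so the eligibility rule
yields roughly 34 and 37 transitions; with a few dozen Bernoulli events the
recovered negative-transition percentages scatter around 65 % / 21 % with a
binomial SE of 7–8 points.  The warmth analysis uses 7 subjects per preset
with paired 1-h RT/WARM blocks; a 1-h block spans only ~12 bout cycles, so
a single subject's %NREM difference has an SD near 17 points and group
means at n = 7 carry ~6-point SEs — the tests therefore judge the DS null
against its own sampling error rather than a fixed band.

## What the synthetic data does and does not show

The generator reproduces the *structure* the analysis relies on —
state-dependent spectra and EMG, transition-locked temperature drops with
genotype-dependent probability, warmth-dependent NREM occupancy, spikes —
with stationary Gaussian textures and exponential bouts.  It does not
emulate real-world scoring difficulty: gradual state transitions, arousals,
movement artifacts, electrode drift, circadian structure, or seizures.
Passing recovery tests therefore demonstrates that the pipeline is
correct and unbiased under its stated model, not that the rule-based scorer
would reach 99 % accuracy on animal recordings (human-level agreement on
real data is ~90 %, which is why thresholds are refit per recording and a
consensus mechanism exists).

## Degenerate inputs and numerical conventions

Zero-duration sessions yield empty recordings without error; all-zero
epochs carry a NaN theta/delta ratio and fall to quiet wake; a zero-power
PSD makes the delta ratio an error (undefined), as does a band containing
no frequency bins.  Threshold fitting requires ≥ 100 epochs and errors on
(near-)constant features.  EDF writing quantizes each channel to 16 bits
over a symmetric physical range derived from its own extremum (round-trip
error ≤ 1 step) and requires whole seconds of data at an integer sample
rate.  All randomness flows through numpy Generators seeded from explicit
session seeds; cohorts derive per-subject seeds from a master seed via
SeedSequence spawning, so identical master seeds give byte-identical
manifests.
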