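"""Synthetic polysomnography generator with genotype presets.

Every downstream stage of the pipeline is exercised on sessions produced
here: a semi-Markov (alternating-renewal) vigilance-state process on a 5-s
epoch grid, state-gated ECoG/LFP and EMG channels, a 1 Hz core-temperature
trace with probabilistic drops time-locked to NREM onsets, and optional
interictal spikes.  Ground truth (hypnogram, onset times, injected drops,
spike times) is returned alongside every session so recovery can be tested.

Genotype presets encode the study conditions being emulated:

``WT``
    Wake→NREM transitions are accompanied by a core-temperature drop with
    probability 0.65; NREM carries a clear delta surge (delta amplitude gain
    3× wake); warmth raises the expected NREM fraction; no interictal
    spikes.
``DS``
    Dravet-syndrome model: temperature-drop probability 0.21, no NREM delta
    surge (gain ≈ 1), no warmth response, lower baseline temperature, and a
    nonzero interictal-spike rate.
``DS_RESCUED``
    DS after hypothalamic Na\\ :sub:`V`\\ 1.1 restoration: warmth response and
    delta surge equal to WT's, DS-like spike rate and baseline temperature.

The warmth effect is implemented as a change in state-entry probabilities
(an added NREM self-entry mass), which keeps the stationary state occupancy
analytic; :func:`stationary_state_fractions` exposes the closed form used by
the Monte-Carlo tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.optimize import brentq

from .sigio import (
    DEFAULT_EPOCH_S, NREM, REM, WAKE,
    Hypnogram, SignalRecording, TemperatureTrace,
    write_edf, write_hypnogram_csv, write_spike_times_csv, write_temperature_csv,
)

_STATES = (WAKE, NREM, REM)

# acquisition metadata mirrored into every synthetic recording
_ACQ_METADATA = {"bandpass_hz": (0.5, 100.0), "notch_hz": 50.0}


@dataclass(frozen=True)
class GenotypePreset:
    """Parameter bundle for one genotype/condition.

    ``state_entry_probs[s]`` gives the next-state distribution of the
    embedded jump chain after a bout of state ``s`` ends (self-entries
    allowed; they extend the sojourn).  ``bout_mean_s`` are exponential bout
    means, truncated below at one epoch when realized.
    """

    name: str
    bout_mean_s: dict = field(default_factory=dict)
    state_entry_probs: dict = field(default_factory=dict)
    nrem_delta_gain: float = 3.0
    temp_drop_prob: float = 0.65
    temp_drop_magnitude_c: float = 0.4
    temp_drop_tau_s: float = 60.0
    baseline_temp_c: float = 37.0
    warm_nrem_boost: float = 0.15
    spike_rate_per_min: float = 0.0
    emg_rms_by_state: dict = field(default_factory=dict)
    # signal-model amplitudes (µV RMS), shared across presets
    ecog_background_rms_uv: float = 20.0
    delta_wake_rms_uv: float = 8.0
    theta_rem_rms_uv: float = 30.0
    # temperature-trace nuisance parameters
    temp_noise_sd_c: float = 0.03
    temp_drift_amplitude_c: float = 0.08
    temp_drift_period_s: float = 2400.0

    def __post_init__(self):
        for p in (self.temp_drop_prob,):
            if not 0.0 <= p <= 1.0:
                raise ValueError("temp_drop_prob must lie in [0, 1]")
        if not 34.0 <= self.baseline_temp_c <= 39.0:
            raise ValueError("baseline_temp_c must lie in [34, 39] degC")
        if self.spike_rate_per_min < 0:
            raise ValueError("spike_rate_per_min must be non-negative")
        for s, row in self.state_entry_probs.items():
            tot = sum(row.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"state_entry_probs[{s}] sums to {tot}, expected 1")
        for s, m in self.bout_mean_s.items():
            if m <= DEFAULT_EPOCH_S:
                raise ValueError(f"bout_mean_s[{s}] must exceed the {DEFAULT_EPOCH_S} s epoch")


_COMMON = dict(
    bout_mean_s={WAKE: 150.0, NREM: 150.0, REM: 30.0},
    state_entry_probs={
        WAKE: {WAKE: 0.0, NREM: 1.0, REM: 0.0},
        NREM: {WAKE: 0.95, NREM: 0.0, REM: 0.05},
        REM: {WAKE: 1.0, NREM: 0.0, REM: 0.0},
    },
    emg_rms_by_state={WAKE: 30.0, NREM: 8.0, REM: 4.0},
)

_PRESETS = {
    "WT": GenotypePreset(
        name="WT", nrem_delta_gain=3.0, temp_drop_prob=0.65,
        baseline_temp_c=37.0, warm_nrem_boost=0.15, spike_rate_per_min=0.0,
        **_COMMON,
    ),
    "DS": GenotypePreset(
        name="DS", nrem_delta_gain=1.0, temp_drop_prob=0.21,
        baseline_temp_c=36.2, warm_nrem_boost=0.0, spike_rate_per_min=1.0,
        **_COMMON,
    ),
    "DS_RESCUED": GenotypePreset(
        name="DS_RESCUED", nrem_delta_gain=3.0, temp_drop_prob=0.65,
        baseline_temp_c=36.2, warm_nrem_boost=0.15, spike_rate_per_min=1.0,
        **_COMMON,
    ),
}


def make_preset(name: str, **overrides) -> GenotypePreset:
    """Return the named genotype preset, optionally overriding fields."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; valid presets: {sorted(_PRESETS)}")
    preset = _PRESETS[name]
    return replace(preset, **overrides) if overrides else preset


@dataclass
class SessionSpec:
    """One recording session: subject, preset, ambient-temperature blocks."""

    subject_id: str
    preset: GenotypePreset
    duration_s: float
    sample_rate_hz: float = 250.0
    ambient_blocks: list = field(default_factory=list)  # [(label "RT"|"WARM", duration_s)]
    seed: int = 0

    def __post_init__(self):
        if not self.ambient_blocks:
            self.ambient_blocks = [("RT", self.duration_s)]
        total = sum(d for _, d in self.ambient_blocks)
        if abs(total - self.duration_s) > 1e-9:
            raise ValueError(
                f"block durations sum to {total} s but duration_s is {self.duration_s} s"
            )
        for lbl, _ in self.ambient_blocks:
            if lbl not in ("RT", "WARM"):
                raise ValueError(f"ambient block label must be RT or WARM, got {lbl!r}")
        if self.sample_rate_hz <= 200.0:
            raise ValueError("sample_rate_hz must exceed 200 Hz (Nyquist above 99 Hz)")


@dataclass
class GroundTruth:
    """Everything the generator knows that an analysis should recover."""

    hypnogram: Hypnogram
    nrem_onsets_s: np.ndarray
    temp_drop_onsets_s: np.ndarray
    spike_times_s: np.ndarray


@dataclass
class SyntheticSession:
    spec: SessionSpec
    recording: SignalRecording
    temperature: TemperatureTrace
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# Semi-Markov hypnogram
# ---------------------------------------------------------------------------

def _mean_bout_epochs(bout_mean_s: float, epoch_s: float) -> float:
    # E[ceil(Exp(mu)/e)] = 1 / (1 - exp(-e/mu))
    return 1.0 / (1.0 - np.exp(-epoch_s / bout_mean_s))


def _entry_matrix(preset: GenotypePreset) -> np.ndarray:
    P = np.zeros((3, 3))
    for i, s in enumerate(_STATES):
        for j, t in enumerate(_STATES):
            P[i, j] = preset.state_entry_probs[s].get(t, 0.0)
    return P


def _occupancy(P: np.ndarray, mean_epochs: np.ndarray) -> np.ndarray:
    # stationary distribution of the embedded chain, then time-weighting
    w, v = np.linalg.eig(P.T)
    pi = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    pi = pi / pi.sum()
    occ = pi * mean_epochs
    return occ / occ.sum()


def _warm_matrix(P: np.ndarray, lam: float) -> np.ndarray:
    """Move entry mass toward NREM: every row's non-NREM mass shrinks by (1-lam)."""
    Q = P.copy()
    i_n = _STATES.index(NREM)
    for i in range(3):
        non = 1.0 - Q[i, i_n]
        Q[i, i_n] = Q[i, i_n] + lam * non
        for j in range(3):
            if j != i_n:
                Q[i, j] *= (1.0 - lam)
    return Q


def _block_matrices(preset: GenotypePreset, epoch_s: float) -> dict:
    """Entry matrices per ambient block, warm block tuned to the NREM boost."""
    P = _entry_matrix(preset)
    m = np.array([_mean_bout_epochs(preset.bout_mean_s[s], epoch_s) for s in _STATES])
    out = {"RT": P}
    boost = preset.warm_nrem_boost
    if boost == 0.0:
        out["WARM"] = P
        return out
    i_n = _STATES.index(NREM)
    base = _occupancy(P, m)[i_n]
    target = base + boost
    if target >= 1.0:
        raise ValueError("warm_nrem_boost pushes NREM occupancy past 1")

    def f(lam):
        return _occupancy(_warm_matrix(P, lam), m)[i_n] - target

    lam = brentq(f, 0.0, 0.999999)
    out["WARM"] = _warm_matrix(P, lam)
    return out


def stationary_state_fractions(preset: GenotypePreset, block: str = "RT",
                               epoch_length_s: float = DEFAULT_EPOCH_S) -> dict:
    """Analytic stationary occupancy of each state for the given ambient block."""
    P = _block_matrices(preset, epoch_length_s)[block]
    m = np.array([_mean_bout_epochs(preset.bout_mean_s[s], epoch_length_s) for s in _STATES])
    occ = _occupancy(P, m)
    return dict(zip(_STATES, occ))


def simulate_hypnogram(spec: SessionSpec, rng: np.random.Generator | None = None,
                       epoch_length_s: float = DEFAULT_EPOCH_S) -> Hypnogram:
    """Draw one ground-truth hypnogram from the preset's alternating-bout model.

    Bout lengths are exponential (mean per state), truncated below at one
    epoch; next states follow the embedded entry matrix, which differs
    between RT and WARM blocks so that warm blocks carry ``warm_nrem_boost``
    extra expected NREM occupancy.  Sessions start awake.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n_total = spec.duration_s / epoch_length_s
    if abs(n_total - round(n_total)) > 1e-9:
        raise ValueError("duration_s must be a whole number of epochs")
    n_total = int(round(n_total))
    matrices = _block_matrices(spec.preset, epoch_length_s)
    block_edges = np.cumsum([0.0] + [d for _, d in spec.ambient_blocks]) / epoch_length_s
    block_edges = np.round(block_edges).astype(int)

    labels = np.empty(n_total, dtype="<U10")
    state = 0  # WAKE
    pos = 0
    for b, (blabel, _) in enumerate(spec.ambient_blocks):
        end = block_edges[b + 1]
        while pos < end:
            mean_s = spec.preset.bout_mean_s[_STATES[state]]
            k = max(1, int(np.ceil(rng.exponential(mean_s) / epoch_length_s)))
            k = min(k, end - pos)
            labels[pos:pos + k] = _STATES[state]
            pos += k
            state = rng.choice(3, p=matrices[blabel][state])
    return Hypnogram(labels, epoch_length_s, provenance="ground_truth")


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def _pink_noise(n: int, fs: float, rng: np.random.Generator, rms: float,
                corner_hz: float = 0.5) -> np.ndarray:
    """1/f-power noise, flattened below ``corner_hz``, scaled to target RMS."""
    if n == 0:
        return np.zeros(0)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = np.ones_like(freqs)
    pos = freqs > 0
    shaping[pos] = 1.0 / np.sqrt(np.maximum(freqs[pos], corner_hz))
    shaping[0] = 0.0
    spec = (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))) * shaping
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _band_noise(n: int, fs: float, lo: float, hi: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [lo, hi] Hz."""
    if n == 0:
        return np.zeros(0)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _state_envelope(hypnogram: Hypnogram, values: dict, fs: float,
                    ramp_s: float = 0.5) -> np.ndarray:
    """Per-sample amplitude envelope from per-state values, cross-faded <= 1 s."""
    n_per = int(round(hypnogram.epoch_length_s * fs))
    env = np.repeat([values.get(lbl, 0.0) for lbl in hypnogram.labels], n_per)
    if env.size == 0:
        return env
    k = max(1, int(round(ramp_s * fs)))
    kernel = np.hanning(2 * k + 1)
    kernel /= kernel.sum()
    return np.convolve(env, kernel, mode="same")


def synthesize_signals(hypnogram: Hypnogram, preset: GenotypePreset,
                       spec: SessionSpec, rng: np.random.Generator | None = None
                       ) -> SignalRecording:
    """Render ECoG/LFP and EMG channels for a hypnogram.

    ECoG/LFP = pink-noise background + a 0.5–4 Hz narrowband oscillator whose
    amplitude is ``delta_wake_rms_uv`` in wake and ``nrem_delta_gain`` times
    that in NREM + a 4–8 Hz oscillator active in REM.  EMG = band-limited
    noise with per-state RMS.  State switches are cross-faded over 0.5 s.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    fs = spec.sample_rate_hz
    n = int(round(hypnogram.duration_s * fs))
    if abs(hypnogram.duration_s - spec.duration_s) > hypnogram.epoch_length_s:
        raise ValueError("hypnogram duration does not match the session spec")
    meta = {**_ACQ_METADATA, "genotype": preset.name,
            "ambient_blocks": list(spec.ambient_blocks)}
    if n == 0:
        return SignalRecording([("ECoG", np.zeros(0)), ("EMG", np.zeros(0))],
                               fs, spec.subject_id, meta)

    ecog = _pink_noise(n, fs, rng, preset.ecog_background_rms_uv)
    delta_env = _state_envelope(
        hypnogram,
        {WAKE: preset.delta_wake_rms_uv,
         NREM: preset.delta_wake_rms_uv * preset.nrem_delta_gain,
         REM: 0.0},
        fs,
    )
    ecog += _band_noise(n, fs, 0.5, 4.0, rng) * delta_env
    theta_env = _state_envelope(hypnogram, {REM: preset.theta_rem_rms_uv}, fs)
    ecog += _band_noise(n, fs, 4.0, 8.0, rng) * theta_env

    emg_hi = min(100.0, 0.45 * fs)
    emg = _band_noise(n, fs, 20.0, emg_hi, rng) * _state_envelope(
        hypnogram, preset.emg_rms_by_state, fs)

    return SignalRecording([("ECoG", ecog), ("EMG", emg)], fs, spec.subject_id, meta)


# ---------------------------------------------------------------------------
# Temperature
# ---------------------------------------------------------------------------

def nrem_onset_times(hypnogram: Hypnogram) -> np.ndarray:
    """Start times (s) of every NREM bout (epoch whose predecessor is not NREM)."""
    is_n = hypnogram.labels == NREM
    if is_n.size == 0:
        return np.empty(0)
    onsets = np.flatnonzero(is_n & ~np.concatenate(([False], is_n[:-1])))
    return onsets * hypnogram.epoch_length_s


def synthesize_temperature(hypnogram: Hypnogram, preset: GenotypePreset,
                           spec: SessionSpec, rng: np.random.Generator | None = None,
                           noise_sd_c: float | None = None,
                           drift_amplitude_c: float | None = None,
                           ) -> tuple[TemperatureTrace, np.ndarray, np.ndarray]:
    """1 Hz core-temperature trace with drops time-locked to NREM onsets.

    Around ``baseline_temp_c`` the trace carries a slow sinusoidal drift and
    white measurement noise.  At each NREM onset, independently with
    probability ``temp_drop_prob``, an exponential drop of
    ``temp_drop_magnitude_c`` (time constant ``temp_drop_tau_s``) is
    superimposed for the duration of the NREM bout, recovering with twice
    the time constant afterwards.

    Returns ``(trace, nrem_onsets_s, drop_onsets_s)``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 2)
    noise_sd = preset.temp_noise_sd_c if noise_sd_c is None else noise_sd_c
    drift_amp = preset.temp_drift_amplitude_c if drift_amplitude_c is None else drift_amplitude_c

    n = int(round(hypnogram.duration_s))
    t = np.arange(n, dtype=float)
    phase = rng.uniform(0, 2 * np.pi)
    temp = preset.baseline_temp_c + drift_amp * np.sin(
        2 * np.pi * t / preset.temp_drift_period_s + phase)

    onsets = nrem_onset_times(hypnogram)
    epoch_s = hypnogram.epoch_length_s
    is_n = hypnogram.labels == NREM
    drop_mask = rng.random(len(onsets)) < preset.temp_drop_prob
    tau, tau_rec = preset.temp_drop_tau_s, 2.0 * preset.temp_drop_tau_s
    for onset_s, has_drop in zip(onsets, drop_mask):
        if not has_drop:
            continue
        i0 = int(round(onset_s / epoch_s))
        i1 = i0
        while i1 < len(is_n) and is_n[i1]:
            i1 += 1
        t_end = i1 * epoch_s
        during = (t >= onset_s) & (t < t_end)
        temp[during] -= preset.temp_drop_magnitude_c * (
            1.0 - np.exp(-(t[during] - onset_s) / tau))
        depth_end = preset.temp_drop_magnitude_c * (1.0 - np.exp(-(t_end - onset_s) / tau))
        after = t >= t_end
        temp[after] -= depth_end * np.exp(-(t[after] - t_end) / tau_rec)

    if noise_sd > 0:
        temp += rng.normal(0.0, noise_sd, size=n)
    trace = TemperatureTrace(t, temp)
    return trace, onsets, onsets[drop_mask]


# ---------------------------------------------------------------------------
# Interictal spikes
# ---------------------------------------------------------------------------

def _spike_waveform(fs: float, width_s: float = 0.06) -> np.ndarray:
    """Biphasic Gaussian-derivative pulse, unit peak amplitude, < 100 ms.

    The Gaussian SD is width/7.5 (8 ms at the default width), putting the
    pulse's spectral peak near 20 Hz — clearly separated from the delta and
    theta bands that carry the state information.
    """
    sigma = width_s / 7.5
    t = np.arange(-width_s / 2, width_s / 2, 1.0 / fs)
    w = -(t / sigma) * np.exp(-t ** 2 / (2 * sigma ** 2))
    return w / np.max(np.abs(w))


def inject_interictal_spikes(recording: SignalRecording, preset: GenotypePreset,
                             seed: int | np.random.Generator = 0,
                             channel: str = "ECoG",
                             amplitude_sd: float = 6.0,
                             ) -> tuple[SignalRecording, np.ndarray]:
    """Add brief biphasic transients at Poisson times on the ECoG/LFP channel.

    Spike peak amplitude is ``amplitude_sd`` times the robust (MAD-based) SD
    of the spike-free signal.  A zero rate returns the recording unchanged.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rate = preset.spike_rate_per_min
    if rate <= 0 or recording.n_samples == 0:
        return recording, np.empty(0)
    fs = recording.sample_rate_hz
    duration = recording.duration_s
    n_spikes = rng.poisson(rate * duration / 60.0)
    times = np.sort(rng.uniform(0.05, duration - 0.05, size=n_spikes))

    x = recording.channel(channel).copy()
    robust_sd = 1.4826 * np.median(np.abs(x - np.median(x)))
    w = _spike_waveform(fs) * amplitude_sd * robust_sd
    half = len(w) // 2
    for ts in times:
        i = int(round(ts * fs))
        lo, hi = i - half, i - half + len(w)
        if lo < 0 or hi > len(x):
            continue
        x[lo:hi] += w
    channels = [(lbl, x if lbl == channel else arr) for lbl, arr in recording.channels]
    out = SignalRecording(channels, fs, recording.subject_id, dict(recording.metadata))
    return out, times


# ---------------------------------------------------------------------------
# Sessions and cohorts
# ---------------------------------------------------------------------------

def generate_session(spec: SessionSpec) -> SyntheticSession:
    """Generate one full session (signals, temperature, ground truth) from a spec."""
    ss = np.random.SeedSequence(spec.seed)
    rng_h, rng_sig, rng_temp, rng_spk = (np.random.default_rng(c) for c in ss.spawn(4))
    hyp = simulate_hypnogram(spec, rng_h)
    rec = synthesize_signals(hyp, spec.preset, spec, rng_sig)
    trace, onsets, drop_onsets = synthesize_temperature(hyp, spec.preset, spec, rng_temp)
    rec, spike_times = inject_interictal_spikes(rec, spec.preset, rng_spk)
    gt = GroundTruth(hyp, onsets, drop_onsets, spike_times)
    return SyntheticSession(spec, rec, trace, gt)


def generate_cohort(group_specs, seed: int, out_dir=None,
                    sample_rate_hz: float = 250.0) -> list[SyntheticSession]:
    """Generate a multi-group cohort with deterministic per-subject seeds.

    ``group_specs`` is a list of ``(preset_or_name, n_subjects,
    ambient_blocks)`` tuples.  When ``out_dir`` is given, each session is
    written to disk (EDF + CSVs) together with a ``manifest.json`` listing
    every file and the ground truth; identical master seeds yield
    byte-identical manifests.
    """
    master = np.random.SeedSequence(seed)
    sessions: list[SyntheticSession] = []
    manifest = {"master_seed": int(seed), "sessions": []}
    total = sum(int(n) for _, n, _ in group_specs)
    children = master.spawn(total)
    k = 0
    for gi, (preset, n_subjects, blocks) in enumerate(group_specs):
        if isinstance(preset, str):
            preset = make_preset(preset)
        if n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")
        for si in range(int(n_subjects)):
            subject_id = f"{preset.name}-g{gi}-s{si + 1:02d}"
            sub_seed = int(children[k].generate_state(1)[0] % (2 ** 31))
            k += 1
            spec = SessionSpec(
                subject_id=subject_id, preset=preset,
                duration_s=float(sum(d for _, d in blocks)),
                sample_rate_hz=sample_rate_hz,
                ambient_blocks=list(blocks), seed=sub_seed,
            )
            session = generate_session(spec)
            sessions.append(session)
            entry = {
                "subject_id": subject_id,
                "preset": preset.name,
                "seed": sub_seed,
                "duration_s": spec.duration_s,
                "ambient_blocks": [[lbl, float(d)] for lbl, d in blocks],
                "nrem_onsets_s": [float(v) for v in session.ground_truth.nrem_onsets_s],
                "temp_drop_onsets_s": [float(v) for v in session.ground_truth.temp_drop_onsets_s],
                "n_spikes": int(len(session.ground_truth.spike_times_s)),
            }
            if out_dir is not None:
                out_dir = Path(out_dir)
                out_dir.mkdir(parents=True, exist_ok=True)
                files = {
                    "edf": f"{subject_id}.edf",
                    "temperature_csv": f"{subject_id}_temp.csv",
                    "hypnogram_csv": f"{subject_id}_hypnogram.csv",
                    "spikes_csv": f"{subject_id}_spikes.csv",
                }
                write_edf(session.recording, out_dir / files["edf"])
                write_temperature_csv(session.temperature, out_dir / files["temperature_csv"])
                write_hypnogram_csv(session.ground_truth.hypnogram,
                                    out_dir / files["hypnogram_csv"])
                write_spike_times_csv(session.ground_truth.spike_times_s,
                                      out_dir / files["spikes_csv"])
                entry["files"] = files
            manifest["sessions"].append(entry)
    if out_dir is not None:
        (Path(out_dir) / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True))
    return sessions
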