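"""Rule-based vigilance-state scoring of 5-s epochs.

The decision cascade per epoch mirrors how rodent polysomnography is scored
by eye, with EMG as the primary wake discriminator:

1. ``ARTIFACT`` if the artifact flag is set;
2. ``WAKE`` if EMG RMS exceeds the wake threshold (active wake);
3. ``REM`` if the theta (4–8 Hz) to delta (0.5–4 Hz) power ratio exceeds
   2.5 and EMG is low relative to NREM;
4. ``NREM`` if delta power exceeds the delta threshold;
5. ``WAKE`` otherwise (quiet-wake fallback).

Thresholds are fitted per recording: the EMG threshold is an Otsu
(two-class) split on log EMG RMS; the delta threshold is an Otsu split on
log delta power of the low-EMG epochs, falling back to a low quantile when
no usable two-mode structure exists — in Dravet-model recordings the NREM
delta surge is absent, so low-EMG epochs cannot be separated by delta power
and the EMG criterion has to carry the classification.

Runs where wake and NREM alternate within 20 s (4 epochs) are relabelled
``TRANSITION`` by :func:`apply_transition_rule`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .sigio import (ARTIFACT, DEFAULT_EPOCH_S, NREM, REM, TRANSITION, WAKE,
                    Hypnogram, SignalRecording)
from .spectral import BANDS, SpectralBands

logger = logging.getLogger(__name__)

#: theta/delta ratio above which a low-EMG epoch is scored REM
REM_THETA_DELTA_THRESHOLD = 2.5


@dataclass
class EpochFeatures:
    """Spectral and EMG features of one scoring epoch."""

    epoch_index: int
    delta_power: float  # µV², 0.5–4 Hz
    theta_power: float  # µV², 4–8 Hz
    theta_delta_ratio: float  # NaN when delta power is zero
    total_power: float  # µV²
    emg_rms: float  # µV
    artifact_flag: bool = False


@dataclass
class ScoringThresholds:
    emg_wake_threshold: float  # µV
    delta_nrem_threshold: float  # µV²
    rem_theta_delta_threshold: float = REM_THETA_DELTA_THRESHOLD
    artifact_amplitude_sd: float = 8.0


def _find_channels(recording: SignalRecording,
                   ecog_channel: str | None, emg_channel: str | None):
    labels = recording.channel_labels
    if emg_channel is None:
        emg_candidates = [l for l in labels if "EMG" in l.upper()]
        if not emg_candidates:
            raise ValueError(f"no EMG channel found among {labels}")
        emg_channel = emg_candidates[0]
    if ecog_channel is None:
        others = [l for l in labels if l != emg_channel]
        if not others:
            raise ValueError("recording has no ECoG/LFP channel")
        ecog_channel = others[0]
    return ecog_channel, emg_channel


def _epoch_psd_matrix(x: np.ndarray, fs: float, epoch_s: float):
    """Hann-windowed, mean-detrended periodogram of every epoch (vectorized)."""
    n_per = int(round(epoch_s * fs))
    n_epochs = len(x) // n_per
    segs = x[:n_epochs * n_per].reshape(n_epochs, n_per)
    freqs, pxx = sps.welch(segs, fs=fs, window="hann", nperseg=n_per,
                           noverlap=0, detrend="constant", scaling="density",
                           axis=-1)
    return freqs, pxx


def compute_epoch_features(recording: SignalRecording,
                           epoch_length_s: float = DEFAULT_EPOCH_S,
                           ecog_channel: str | None = None,
                           emg_channel: str | None = None,
                           bands: SpectralBands = BANDS) -> list[EpochFeatures]:
    """Per-epoch delta/theta/total power (ECoG/LFP) and EMG RMS.

    Band powers use the display delta band (0.5–4 Hz) and theta (4–8 Hz)
    with the bin-center convention of :mod:`somnotherm.spectral`; the EMG
    channel is assumed band-limited by the acquisition filter and its RMS is
    taken directly.
    """
    ecog_channel, emg_channel = _find_channels(recording, ecog_channel, emg_channel)
    fs = recording.sample_rate_hz
    ecog = recording.channel(ecog_channel)
    emg = recording.channel(emg_channel)
    n_per = int(round(epoch_length_s * fs))
    n_epochs = len(ecog) // n_per

    freqs, pxx = _epoch_psd_matrix(ecog, fs, epoch_length_s)
    df = freqs[1] - freqs[0]
    delta_m = (freqs >= bands.delta_display[0]) & (freqs <= bands.delta_display[1])
    theta_m = (freqs >= bands.theta[0]) & (freqs <= bands.theta[1])
    delta = pxx[:, delta_m].sum(axis=1) * df
    theta = pxx[:, theta_m].sum(axis=1) * df
    total = pxx.sum(axis=1) * df
    emg_rms = np.sqrt(
        np.mean(emg[:n_epochs * n_per].reshape(n_epochs, n_per) ** 2, axis=1))

    out = []
    for k in range(n_epochs):
        ratio = theta[k] / delta[k] if delta[k] > 0 else float("nan")
        out.append(EpochFeatures(k, float(delta[k]), float(theta[k]), ratio,
                                 float(total[k]), float(emg_rms[k])))
    return out


def _otsu_log_threshold(values: np.ndarray, n_bins: int = 64):
    """Otsu split on log10 values; returns (threshold, separation).

    ``separation`` is the distance between the two class means in units of
    their average within-class SD — a two-mode distribution scores high, a
    unimodal one low.
    """
    v = np.log10(values[values > 0])
    if v.size < 2 or np.ptp(v) < 1e-9:
        raise ValueError("features are (near-)constant; supply thresholds manually")
    hist, edges = np.histogram(v, bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2
    w = hist.astype(float)
    total = w.sum()
    cum_w = np.cumsum(w)
    cum_m = np.cumsum(w * centers)
    between = np.full(n_bins, -1.0)
    for i in range(1, n_bins):
        w0, w1 = cum_w[i - 1], total - cum_w[i - 1]
        if w0 == 0 or w1 == 0:
            continue
        mu0 = cum_m[i - 1] / w0
        mu1 = (cum_m[-1] - cum_m[i - 1]) / w1
        between[i] = w0 * w1 * (mu0 - mu1) ** 2
    # the maximum is flat across an empty valley; split at the valley center
    peak = between.max()
    at_peak = np.flatnonzero(between >= peak * (1 - 1e-9))
    best_t = float(edges[int(round(at_peak.mean()))])
    lo, hi = v[v < best_t], v[v >= best_t]
    if lo.size < 2 or hi.size < 2:
        separation = 0.0
    else:
        sd = (lo.std() + hi.std()) / 2
        separation = (hi.mean() - lo.mean()) / sd if sd > 0 else np.inf
    return 10.0 ** best_t, separation


def fit_thresholds(features: list[EpochFeatures],
                   min_epochs: int = 100,
                   delta_separation_min: float = 3.0) -> ScoringThresholds:
    """Fit EMG and delta thresholds from the epoch-feature distributions.

    EMG: Otsu valley on log EMG RMS (wake vs sleep).  Delta: Otsu valley on
    log delta power of low-EMG epochs; when the two Otsu classes are
    separated by less than ``delta_separation_min`` within-class SDs the
    distribution is treated as single-mode (no delta surge) and the
    threshold falls back below the 1st percentile, so that low-EMG epochs
    are scored NREM on the strength of the EMG criterion alone.
    """
    if len(features) < min_epochs:
        raise ValueError(f"need at least {min_epochs} epochs to fit thresholds "
                         f"(got {len(features)})")
    emg = np.array([f.emg_rms for f in features])
    delta = np.array([f.delta_power for f in features])
    emg_thr, _ = _otsu_log_threshold(emg)
    low_emg_delta = delta[(emg <= emg_thr) & (delta > 0)]
    if low_emg_delta.size < 10:
        # essentially no sleep in the recording; any delta criterion works
        delta_thr = float(np.quantile(delta[delta > 0], 0.01)) * 0.5
        return ScoringThresholds(float(emg_thr), delta_thr)
    delta_thr, separation = _otsu_log_threshold(low_emg_delta)
    if separation < delta_separation_min:
        delta_thr = float(np.quantile(low_emg_delta, 0.01)) * 0.5
        logger.info("no two-mode delta structure among low-EMG epochs "
                    "(separation %.2f); delta threshold set below the "
                    "distribution, scoring driven by EMG", separation)
    return ScoringThresholds(float(emg_thr), float(delta_thr))


def classify_epochs(features: list[EpochFeatures],
                    thresholds: ScoringThresholds,
                    epoch_length_s: float = DEFAULT_EPOCH_S) -> Hypnogram:
    """Apply the decision cascade; returns a scored hypnogram.

    REM additionally requires EMG at or below the median EMG of the NREM
    epochs from a provisional pass ("low EMG relative to NREM"); epochs
    failing that fall through to the delta rule.
    """
    labels = np.empty(len(features), dtype="<U10")

    def cascade(f: EpochFeatures, rem_emg_max: float | None) -> str:
        if f.artifact_flag:
            return ARTIFACT
        if f.emg_rms > thresholds.emg_wake_threshold:
            return WAKE
        ratio_ok = (np.isfinite(f.theta_delta_ratio)
                    and f.theta_delta_ratio > thresholds.rem_theta_delta_threshold)
        if ratio_ok and (rem_emg_max is None or f.emg_rms <= rem_emg_max):
            return REM
        if f.delta_power > thresholds.delta_nrem_threshold:
            return NREM
        return WAKE

    provisional = [cascade(f, None) for f in features]
    nrem_emg = [f.emg_rms for f, lbl in zip(features, provisional) if lbl == NREM]
    rem_emg_max = float(np.median(nrem_emg)) if nrem_emg else None
    for i, f in enumerate(features):
        labels[i] = cascade(f, rem_emg_max)
    return Hypnogram(labels, epoch_length_s, provenance="scored")


def apply_transition_rule(hypnogram: Hypnogram,
                          window_epochs: int = 4) -> Hypnogram:
    """Relabel wake/NREM alternation runs as ``TRANSITION``.

    A maximal sequence of consecutive wake/NREM runs, each no longer than
    ``window_epochs`` epochs (20 s inclusive), containing at least one
    same-state recurrence (three or more runs) is relabelled TRANSITION.
    Stable runs (longer than the window) and clean single switches are left
    untouched.  Idempotent.
    """
    labels = hypnogram.labels.copy()
    n = len(labels)
    # run-length encode
    runs = []  # (start, length, label)
    i = 0
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        runs.append((i, j - i, labels[i]))
        i = j
    # group consecutive short wake/NREM runs
    k = 0
    while k < len(runs):
        start_k = k
        group = []
        while (k < len(runs) and runs[k][2] in (WAKE, NREM)
               and runs[k][1] <= window_epochs):
            group.append(runs[k])
            k += 1
        if len(group) >= 3 and {r[2] for r in group} == {WAKE, NREM}:
            for s, ln, _ in group:
                labels[s:s + ln] = TRANSITION
        if k == start_k:
            k += 1
    return Hypnogram(labels, hypnogram.epoch_length_s, hypnogram.provenance)


def detect_artifacts(recording: SignalRecording,
                     features: list[EpochFeatures],
                     ecog_channel: str | None = None,
                     amplitude_sd: float = 8.0,
                     power_percentile: float = 99.9) -> np.ndarray:
    """Flag epochs with extreme ECoG amplitude or total power.

    An epoch is flagged when its peak absolute ECoG amplitude exceeds
    ``amplitude_sd`` robust (MAD-based) SDs of the whole channel, or its
    total power strictly exceeds the ``power_percentile`` percentile across
    epochs.  Flags are written back onto the features.
    """
    if ecog_channel is None:
        non_emg = [l for l in recording.channel_labels if "EMG" not in l.upper()]
        ecog_channel = non_emg[0] if non_emg else recording.channel_labels[0]
    x = recording.channel(ecog_channel)
    if x.size == 0 or not features:
        return np.zeros(len(features), dtype=bool)
    robust_sd = 1.4826 * np.median(np.abs(x - np.median(x)))
    n_per = x.size // len(features) if len(features) else 1
    flags = np.zeros(len(features), dtype=bool)
    if robust_sd > 0:
        peaks = np.abs(x[:len(features) * n_per]).reshape(len(features), n_per).max(axis=1)
        flags |= peaks > amplitude_sd * robust_sd
    totals = np.array([f.total_power for f in features])
    if np.any(totals > 0):
        flags |= totals > np.percentile(totals, power_percentile)
    for f, fl in zip(features, flags):
        f.artifact_flag = bool(fl)
    return flags


def score_agreement(h1: Hypnogram, h2: Hypnogram) -> tuple[float, np.ndarray]:
    """Percent label agreement (ARTIFACT epochs excluded from the denominator).

    Returns ``(percent, mask)`` where ``mask`` marks mutually agreed epochs
    for downstream filtering, emulating the dual-scorer consensus step.
    """
    if h1.n_epochs != h2.n_epochs or h1.epoch_length_s != h2.epoch_length_s:
        raise ValueError("hypnograms are on different epoch grids")
    agree = h1.labels == h2.labels
    denom = ~((h1.labels == ARTIFACT) | (h2.labels == ARTIFACT))
    percent = 100.0 * agree[denom].mean() if denom.any() else float("nan")
    return float(percent), agree


def percent_time_in_state(hypnogram: Hypnogram, state: str,
                          interval: tuple[float, float] | None = None) -> float:
    """Percent of non-ARTIFACT epochs in ``interval`` labelled ``state``."""
    if interval is None:
        interval = (0.0, hypnogram.duration_s)
    start_s, end_s = interval
    e = hypnogram.epoch_length_s
    i0, i1 = int(np.floor(start_s / e)), int(np.ceil(end_s / e))
    i0, i1 = max(i0, 0), min(i1, hypnogram.n_epochs)
    if i1 <= i0:
        raise ValueError(f"empty interval ({start_s}, {end_s}) s")
    seg = hypnogram.labels[i0:i1]
    denom = (seg != ARTIFACT).sum()
    if denom == 0:
        return float("nan")
    return 100.0 * float((seg == state).sum()) / float(denom)


class VigilanceScorer:
    """Fit/predict-style wrapper around the rule-based scoring cascade.

    ``fit`` derives the per-recording thresholds from epoch features;
    ``predict`` returns a scored :class:`Hypnogram` with the transition rule
    applied.  ``score_recording`` runs the full chain (features, artifact
    detection, threshold fitting, classification) on a recording.
    """

    def __init__(self, epoch_length_s: float = DEFAULT_EPOCH_S,
                 apply_transitions: bool = True,
                 thresholds: ScoringThresholds | None = None):
        self.epoch_length_s = epoch_length_s
        self.apply_transitions = apply_transitions
        self.thresholds = thresholds

    def fit(self, features: list[EpochFeatures]) -> "VigilanceScorer":
        self.thresholds_ = self.thresholds or fit_thresholds(features)
        return self

    def predict(self, features: list[EpochFeatures]) -> Hypnogram:
        hyp = classify_epochs(features, self.thresholds_, self.epoch_length_s)
        if self.apply_transitions:
            hyp = apply_transition_rule(hyp)
        return hyp

    def score_recording(self, recording: SignalRecording) -> Hypnogram:
        features = compute_epoch_features(recording, self.epoch_length_s)
        detect_artifacts(recording, features)
        return self.fit(features).predict(features)
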