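"""Wake→NREM transition detection and transition-locked analysis.

For every eligible sleep onset the analysis extracts a pair of PSDs — a
wake window of 30 s starting 2 min before the onset and a NREM window of
30 s starting 1 min after it — together with their delta ratios, and
classifies the coincident core-temperature change as negative, unchanged or
positive.

Eligibility is forced by the window geometry: the onset must be preceded by
at least 120 s of contiguous wake (TRANSITION epochs are permitted only in
the final 20 s) and followed by at least 90 s of contiguous NREM; analysis
windows of consecutive events never overlap.

The temperature-change classification compares the mean temperature over
the minute before onset with the mean over 1–3 min after onset; a change
smaller in magnitude than ``epsilon_c`` (default 0.1 °C — the "unchanged"
band, a choice of this module, as the source protocol does not quantify it)
counts as unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .sigio import ARTIFACT, NREM, TRANSITION, WAKE, Hypnogram, SignalRecording, TemperatureTrace
from .spectral import PSDEstimate, compute_psd, delta_ratio

logger = logging.getLogger(__name__)

#: wake PSD window: starts this many seconds before the onset
WAKE_WINDOW_START_BEFORE_S = 120.0
#: NREM PSD window: starts this many seconds after the onset
NREM_WINDOW_START_AFTER_S = 60.0
#: duration of each PSD window
PSD_WINDOW_S = 30.0
#: minimum contiguous NREM required after onset (>= 60 + 30 s window)
MIN_NREM_S = 90.0
#: minimum contiguous wake required before onset
MIN_WAKE_S = 120.0
#: trailing part of the pre-onset wake in which TRANSITION epochs are allowed
TRANSITION_TOLERANCE_S = 20.0

NEGATIVE, UNCHANGED, POSITIVE = "negative", "unchanged", "positive"
TEMP_CLASSES = (NEGATIVE, UNCHANGED, POSITIVE)


@dataclass
class TransitionEvent:
    """One eligible wake→NREM onset with its paired spectra and temperature change."""

    subject_id: str
    onset_s: float
    wake_psd: PSDEstimate
    nrem_psd: PSDEstimate
    wake_delta_ratio: float
    nrem_delta_ratio: float
    temp_baseline_c: float = float("nan")
    temp_post_c: float = float("nan")
    temp_delta_c: float = float("nan")
    temp_class: str = UNCHANGED


@dataclass
class SubjectTransitionSummary:
    """Per-mouse averages: each subject contributes one value downstream."""

    subject_id: str
    n_events: int
    mean_wake_psd: PSDEstimate
    mean_nrem_psd: PSDEstimate
    mean_wake_delta_ratio: float
    mean_nrem_delta_ratio: float
    temp_class_counts: dict = field(default_factory=dict)


def find_wake_to_nrem(hypnogram: Hypnogram,
                      min_wake_s: float = MIN_WAKE_S,
                      min_nrem_s: float = MIN_NREM_S,
                      transition_tolerance_s: float = TRANSITION_TOLERANCE_S,
                      ) -> list[float]:
    """Onset times (s) of eligible wake→NREM transitions.

    Requires ``min_wake_s`` of contiguous WAKE before the onset (TRANSITION
    epochs tolerated in the final ``transition_tolerance_s``) and
    ``min_nrem_s`` of contiguous NREM from the onset.  Events whose analysis
    spans (wake window start to NREM window end) would overlap a previously
    accepted event are skipped.
    """
    e = hypnogram.epoch_length_s
    labels = hypnogram.labels
    n_wake = int(round(min_wake_s / e))
    n_nrem = int(round(min_nrem_s / e))
    n_tol = int(round(transition_tolerance_s / e))
    onsets: list[float] = []
    last_end = -np.inf
    for i in range(n_wake, len(labels) - n_nrem + 1):
        if labels[i] != NREM or labels[i - 1] == NREM:
            continue
        if not np.all(labels[i:i + n_nrem] == NREM):
            continue
        pre = labels[i - n_wake:i]
        strict, tol = pre[:n_wake - n_tol], pre[n_wake - n_tol:]
        if not np.all(strict == WAKE):
            continue
        if not np.all(np.isin(tol, (WAKE, TRANSITION))):
            continue
        onset_s = i * e
        if onset_s - min_wake_s < last_end:
            continue
        onsets.append(float(onset_s))
        last_end = onset_s + NREM_WINDOW_START_AFTER_S + PSD_WINDOW_S
    return onsets


def transition_psds(recording: SignalRecording, onset_s: float,
                    channel: str | None = None,
                    ) -> tuple[PSDEstimate, PSDEstimate, float, float]:
    """Paired wake/NREM PSDs and delta ratios around one onset.

    Wake window ``[onset-120, onset-90)`` s, NREM window
    ``[onset+60, onset+90)`` s, both 30 s.
    """
    if channel is None:
        non_emg = [l for l in recording.channel_labels if "EMG" not in l.upper()]
        channel = non_emg[0]
    if onset_s < WAKE_WINDOW_START_BEFORE_S:
        raise ValueError(
            f"onset at {onset_s:g} s is closer than {WAKE_WINDOW_START_BEFORE_S:g} s "
            "to the start of the recording")
    wake_psd = compute_psd(recording, channel,
                           (onset_s - WAKE_WINDOW_START_BEFORE_S, PSD_WINDOW_S))
    nrem_psd = compute_psd(recording, channel,
                           (onset_s + NREM_WINDOW_START_AFTER_S, PSD_WINDOW_S))
    return wake_psd, nrem_psd, delta_ratio(wake_psd), delta_ratio(nrem_psd)


def classify_temperature_change(trace: TemperatureTrace, onset_s: float,
                                epsilon_c: float = 0.1,
                                baseline_window_s: tuple[float, float] = (-60.0, 0.0),
                                post_window_s: tuple[float, float] = (60.0, 180.0),
                                ) -> tuple[str, float]:
    """Classify the core-temperature change at a NREM onset.

    Baseline = mean over the minute before onset; post = mean over 1–3 min
    after.  Negative if the change is below ``-epsilon_c``, positive above
    ``+epsilon_c``, unchanged otherwise.
    """
    baseline = trace.window_mean(onset_s + baseline_window_s[0],
                                 onset_s + baseline_window_s[1])
    post = trace.window_mean(onset_s + post_window_s[0], onset_s + post_window_s[1])
    if np.isnan(baseline) or np.isnan(post):
        raise ValueError(
            f"temperature trace does not cover the analysis windows around "
            f"{onset_s:g} s")
    delta = post - baseline
    if delta < -epsilon_c:
        cls = NEGATIVE
    elif delta > epsilon_c:
        cls = POSITIVE
    else:
        cls = UNCHANGED
    return cls, float(delta)


def _slide_for_artifacts(hypnogram: Hypnogram | None, onset_s: float,
                         max_slide_s: float = 30.0) -> float | None:
    """Earliest artifact-free start for the wake window, sliding back <= 30 s.

    Returns the window start (s) or None when no artifact-free placement
    exists (the event is then dropped).
    """
    default_start = onset_s - WAKE_WINDOW_START_BEFORE_S
    if hypnogram is None:
        return default_start
    e = hypnogram.epoch_length_s
    for shift in np.arange(0.0, max_slide_s + e, e):
        start = default_start - shift
        if start < 0:
            return None
        i0, i1 = int(start / e), int(np.ceil((start + PSD_WINDOW_S) / e))
        if not np.any(hypnogram.labels[i0:i1] == ARTIFACT):
            return start
    return None


def build_transition_events(recording: SignalRecording, hypnogram: Hypnogram,
                            trace: TemperatureTrace | None = None,
                            channel: str | None = None,
                            epsilon_c: float = 0.1,
                            onsets_s: list[float] | None = None,
                            ) -> list[TransitionEvent]:
    """Run the full transition-locked analysis for one session.

    Detects eligible onsets, computes paired PSDs (sliding the wake window
    back by up to 30 s when it overlaps an ARTIFACT epoch), classifies the
    temperature change when a trace is supplied, and asserts the window
    geometry of every emitted event.  Events whose windows cannot be placed
    are dropped with a logged reason.
    """
    if onsets_s is None:
        onsets_s = find_wake_to_nrem(hypnogram)
    if channel is None:
        non_emg = [l for l in recording.channel_labels if "EMG" not in l.upper()]
        channel = non_emg[0]
    events: list[TransitionEvent] = []
    for onset_s in onsets_s:
        wake_start = _slide_for_artifacts(hypnogram, onset_s)
        if wake_start is None:
            logger.info("dropped onset %.0f s: no artifact-free wake window", onset_s)
            continue
        try:
            wake_psd = compute_psd(recording, channel, (wake_start, PSD_WINDOW_S))
            nrem_psd = compute_psd(recording, channel,
                                   (onset_s + NREM_WINDOW_START_AFTER_S, PSD_WINDOW_S))
        except ValueError as exc:
            logger.info("dropped onset %.0f s: %s", onset_s, exc)
            continue
        ev = TransitionEvent(
            subject_id=recording.subject_id, onset_s=float(onset_s),
            wake_psd=wake_psd, nrem_psd=nrem_psd,
            wake_delta_ratio=delta_ratio(wake_psd),
            nrem_delta_ratio=delta_ratio(nrem_psd),
        )
        if trace is not None:
            try:
                cls, dlt = classify_temperature_change(trace, onset_s, epsilon_c)
            except ValueError as exc:
                logger.info("dropped onset %.0f s: %s", onset_s, exc)
                continue
            ev.temp_class = cls
            ev.temp_delta_c = dlt
            ev.temp_baseline_c = trace.window_mean(onset_s - 60.0, onset_s)
            ev.temp_post_c = trace.window_mean(onset_s + 60.0, onset_s + 180.0)
        # window-geometry invariant: asserted, not assumed
        assert ev.nrem_psd.source_window == (onset_s + NREM_WINDOW_START_AFTER_S,
                                             PSD_WINDOW_S)
        assert ev.wake_psd.source_window[1] == PSD_WINDOW_S
        assert ev.wake_psd.source_window[0] <= onset_s - WAKE_WINDOW_START_BEFORE_S
        events.append(ev)
    return events


def per_subject_average(events: list[TransitionEvent]) -> SubjectTransitionSummary:
    """Average all of one subject's events (bin-wise PSD mean, ratio mean)."""
    if not events:
        raise ValueError("cannot summarize an empty event list")
    subjects = {e.subject_id for e in events}
    if len(subjects) > 1:
        raise ValueError(f"events from multiple subjects: {sorted(subjects)}")
    wake_d = np.mean([e.wake_psd.density for e in events], axis=0)
    nrem_d = np.mean([e.nrem_psd.density for e in events], axis=0)
    proto_w, proto_n = events[0].wake_psd, events[0].nrem_psd
    counts = {c: sum(1 for e in events if e.temp_class == c) for c in TEMP_CLASSES}
    return SubjectTransitionSummary(
        subject_id=events[0].subject_id,
        n_events=len(events),
        mean_wake_psd=PSDEstimate(proto_w.freqs_hz, wake_d, proto_w.segment_length_s,
                                  proto_w.overlap_fraction, proto_w.window_name,
                                  (float("nan"), PSD_WINDOW_S)),
        mean_nrem_psd=PSDEstimate(proto_n.freqs_hz, nrem_d, proto_n.segment_length_s,
                                  proto_n.overlap_fraction, proto_n.window_name,
                                  (float("nan"), PSD_WINDOW_S)),
        mean_wake_delta_ratio=float(np.mean([e.wake_delta_ratio for e in events])),
        mean_nrem_delta_ratio=float(np.mean([e.nrem_delta_ratio for e in events])),
        temp_class_counts=counts,
    )


def summarize_by_subject(events: list[TransitionEvent]) -> list[SubjectTransitionSummary]:
    """One :class:`SubjectTransitionSummary` per subject, sorted by id."""
    by_subject: dict[str, list[TransitionEvent]] = {}
    for e in events:
        by_subject.setdefault(e.subject_id, []).append(e)
    return [per_subject_average(evs) for _, evs in sorted(by_subject.items())]


def cohort_mean_delta_ratios(events: list[TransitionEvent],
                             per_subject: bool = True) -> tuple[float, float]:
    """Cohort mean (wake, NREM) delta ratios.

    With ``per_subject=True`` (the convention used downstream) each mouse
    contributes one value; otherwise events are pooled, which weights
    subjects by their event counts.
    """
    if per_subject:
        summaries = summarize_by_subject(events)
        return (float(np.mean([s.mean_wake_delta_ratio for s in summaries])),
                float(np.mean([s.mean_nrem_delta_ratio for s in summaries])))
    return (float(np.mean([e.wake_delta_ratio for e in events])),
            float(np.mean([e.nrem_delta_ratio for e in events])))


def build_transition_contingency(groups: dict):
    """Counts of events per temperature class per group, as a ContingencyTable.

    ``groups`` maps group label → list of :class:`TransitionEvent`.
    """
    from .stats_report import ContingencyTable

    if len(groups) < 2:
        raise ValueError("need at least two groups for a contingency table")
    row_labels = list(groups)
    counts = np.array([
        [sum(1 for e in evs if e.temp_class == c) for c in TEMP_CLASSES]
        for evs in groups.values()
    ], dtype=int)
    return ContingencyTable(row_labels, list(TEMP_CLASSES), counts)
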