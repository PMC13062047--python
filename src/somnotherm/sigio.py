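"""On-disk formats and core data containers.

The pipeline exchanges three kinds of files:

* EDF (European Data Format, 16-bit) for the electrophysiology channels
  (ECoG or depth LFP plus EMG, in microvolts);
* plain CSV for the 1 Hz core-temperature trace (``time_s,temp_c``);
* plain CSV for hypnograms (``epoch_index,start_s,label``).

Writers and readers are paired: everything a writer produces, its reader
accepts and reproduces (up to EDF 16-bit quantization of the declared
physical range).  EDF reading is delegated to :mod:`mne`; the writer is a
minimal EDF implementation kept here because the pipeline only ever needs
plain continuous EDF (no EDF+ annotations).
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

# Vigilance-state vocabulary used throughout the package.
WAKE = "WAKE"
NREM = "NREM"
REM = "REM"
TRANSITION = "TRANSITION"
ARTIFACT = "ARTIFACT"
VALID_LABELS = (WAKE, NREM, REM, TRANSITION, ARTIFACT)

#: epoch length used for vigilance scoring, seconds
DEFAULT_EPOCH_S = 5.0

_EDF_DIGITAL_MAX = 32767


@dataclass
class SignalRecording:
    """Multichannel sampled recording (ECoG/LFP + EMG), amplitudes in µV.

    Parameters
    ----------
    channels
        Ordered ``(label, samples)`` pairs; all sample arrays must have
        equal length.  Amplitude unit is microvolts throughout.
    sample_rate_hz
        Sampling rate in Hz.
    subject_id
        Free-text subject identifier.
    metadata
        Genotype/condition labels and acquisition-filter settings
        (``bandpass_hz`` edges, ``notch_hz``).
    """

    channels: list[tuple[str, np.ndarray]]
    sample_rate_hz: float
    subject_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        self.channels = [(str(lbl), np.asarray(x, dtype=float)) for lbl, x in self.channels]
        lengths = {len(x) for _, x in self.channels}
        if len(lengths) > 1:
            raise ValueError(f"channels have inconsistent lengths: {sorted(lengths)}")
        hi = self.metadata.get("bandpass_hz", (None, None))[1] if "bandpass_hz" in self.metadata else None
        if hi is not None and hi > self.sample_rate_hz / 2:
            raise ValueError("band-pass upper edge exceeds Nyquist frequency")

    @property
    def n_samples(self) -> int:
        return len(self.channels[0][1]) if self.channels else 0

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def channel_labels(self) -> list[str]:
        return [lbl for lbl, _ in self.channels]

    def channel(self, label: str) -> np.ndarray:
        for lbl, x in self.channels:
            if lbl == label:
                return x
        raise KeyError(f"no channel {label!r}; available: {self.channel_labels}")


@dataclass
class TemperatureTrace:
    """Core body temperature time series (°C), nominally sampled at 1 Hz."""

    time_s: np.ndarray
    temp_c: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.temp_c = np.asarray(self.temp_c, dtype=float)
        if self.time_s.shape != self.temp_c.shape:
            raise ValueError("time_s and temp_c must have equal length")
        if self.time_s.size and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")
        if self.temp_c.size and (self.temp_c.min() < 25.0 or self.temp_c.max() > 43.0):
            raise ValueError(
                "temperature outside the physiological range [25, 43] degC "
                f"(observed {self.temp_c.min():.2f}..{self.temp_c.max():.2f})"
            )

    def window_mean(self, start_s: float, end_s: float) -> float:
        """Mean temperature over [start_s, end_s); NaN if no samples fall inside."""
        mask = (self.time_s >= start_s) & (self.time_s < end_s)
        if not mask.any():
            return float("nan")
        return float(self.temp_c[mask].mean())


@dataclass
class Hypnogram:
    """Per-epoch vigilance-state labels on a fixed epoch grid."""

    labels: np.ndarray
    epoch_length_s: float = DEFAULT_EPOCH_S
    provenance: str = "scored"  # "ground_truth" or "scored"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="<U10")
        bad = set(np.unique(self.labels)) - set(VALID_LABELS)
        if bad:
            raise ValueError(f"unknown vigilance labels: {sorted(bad)}")
        if self.epoch_length_s <= 0:
            raise ValueError("epoch_length_s must be positive")

    @property
    def n_epochs(self) -> int:
        return int(self.labels.size)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_length_s

    def epoch_start_s(self, index: int) -> float:
        return index * self.epoch_length_s

    def state_mask(self, state: str) -> np.ndarray:
        return self.labels == state


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def write_edf(recording: SignalRecording, path) -> None:
    """Write a :class:`SignalRecording` as a plain 16-bit EDF file.

    Each channel's physical range is set symmetrically around zero from its
    own extremum, so the quantization step is ``2*max|x| / 65534``; a
    round-trip through :func:`read_edf` reproduces samples within one step.
    The recording length must be an integer number of seconds (the EDF data
    record is one second long).
    """
    recording.__post_init__()  # re-validate (channels may have been mutated)
    path = Path(path)
    n_ch = len(recording.channels)
    if n_ch == 0:
        raise ValueError("recording has no channels")
    fs = recording.sample_rate_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sample rate in Hz")
    fs = int(round(fs))
    n = recording.n_samples
    if n % fs != 0:
        raise ValueError("EDF writer requires a whole number of seconds of data")
    n_records = n // fs

    phys_max = []
    for _, x in recording.channels:
        m = float(np.max(np.abs(x))) if x.size else 0.0
        phys_max.append(m if m > 0 else 1.0)

    header = b""
    header += _edf_field("0", 8)
    header += _edf_field(recording.subject_id or "X", 80)
    header += _edf_field("Startdate 01-JAN-2000", 80)
    header += _edf_field("01.01.00", 8)
    header += _edf_field("00.00.00", 8)
    header += _edf_field(256 * (n_ch + 1), 8)
    header += _edf_field("", 44)
    header += _edf_field(n_records, 8)
    header += _edf_field(1, 8)
    header += _edf_field(n_ch, 4)
    for lbl, _ in recording.channels:
        header += _edf_field(lbl[:16], 16)
    header += b"".join(_edf_field("", 80) for _ in range(n_ch))
    header += b"".join(_edf_field("uV", 8) for _ in range(n_ch))
    header += b"".join(_edf_field(f"{-m:.6g}"[:8], 8) for m in phys_max)
    header += b"".join(_edf_field(f"{m:.6g}"[:8], 8) for m in phys_max)
    header += b"".join(_edf_field(-_EDF_DIGITAL_MAX, 8) for _ in range(n_ch))
    header += b"".join(_edf_field(_EDF_DIGITAL_MAX, 8) for _ in range(n_ch))
    header += b"".join(_edf_field("", 80) for _ in range(n_ch))
    header += b"".join(_edf_field(fs, 8) for _ in range(n_ch))
    header += b"".join(_edf_field("", 32) for _ in range(n_ch))

    digital = []
    for (_, x), m in zip(recording.channels, phys_max):
        # float physical max stored with 6 significant digits; rescale to the
        # stored value so the reader's inverse mapping is exact
        m_stored = float(f"{m:.6g}")
        d = np.clip(np.round(x / m_stored * _EDF_DIGITAL_MAX), -_EDF_DIGITAL_MAX, _EDF_DIGITAL_MAX)
        digital.append(d.astype("<i2").reshape(n_records, fs))

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for d in digital:
                fh.write(d[r].tobytes())


def read_edf(path, metadata: dict | None = None) -> SignalRecording:
    """Read an EDF file into a :class:`SignalRecording` (amplitudes in µV)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"EDF file not found: {path}")
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_v = raw.get_data()  # volts (mne converts the uV physical dimension)
    channels = [(lbl, data_v[i] * 1e6) for i, lbl in enumerate(raw.ch_names)]
    subject = ""
    info_subj = raw.info.get("subject_info") or {}
    subject = info_subj.get("his_id") or info_subj.get("last_name") or ""
    return SignalRecording(
        channels=channels,
        sample_rate_hz=float(raw.info["sfreq"]),
        subject_id=str(subject),
        metadata=dict(metadata or {}),
    )


# ---------------------------------------------------------------------------
# CSV formats
# ---------------------------------------------------------------------------

def write_hypnogram_csv(hypnogram: Hypnogram, path) -> None:
    """Write ``epoch_index,start_s,label`` rows (header included)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch_index", "start_s", "label"])
        for i, lbl in enumerate(hypnogram.labels):
            w.writerow([i, f"{i * hypnogram.epoch_length_s:g}", lbl])


def read_hypnogram_csv(path, epoch_length_s: float = DEFAULT_EPOCH_S,
                       provenance: str = "scored") -> Hypnogram:
    """Read a hypnogram CSV; rejects labels outside the state vocabulary.

    The epoch length is inferred from the ``start_s`` column when at least
    two epochs are present, otherwise ``epoch_length_s`` is used.
    """
    labels: list[str] = []
    starts: list[float] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        rows = [row for row in reader if row]
    if not rows:
        logger.warning("empty hypnogram file %s; returning zero epochs", path)
        return Hypnogram(np.empty(0, dtype="<U10"), epoch_length_s, provenance)
    for rownum, row in enumerate(rows[1:], start=2):
        lbl = row[2].strip()
        if lbl not in VALID_LABELS:
            raise ValueError(
                f"{path}, row {rownum}: unknown label {lbl!r} "
                f"(expected one of {list(VALID_LABELS)})"
            )
        labels.append(lbl)
        starts.append(float(row[1]))
    if len(starts) >= 2:
        epoch_length_s = float(starts[1] - starts[0])
    return Hypnogram(np.array(labels, dtype="<U10"), epoch_length_s, provenance)


def write_temperature_csv(trace: TemperatureTrace, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "temp_c"])
        for t, c in zip(trace.time_s, trace.temp_c):
            w.writerow([f"{t:g}", f"{c:.4f}"])


def read_temperature_csv(path) -> TemperatureTrace:
    """Read ``time_s,temp_c``; validates monotone time and the [25, 43] °C range."""
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two numeric columns (time_s,temp_c)")
    return TemperatureTrace(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))


def write_spike_times_csv(spike_times_s, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["spike_time_s"])
        for t in spike_times_s:
            w.writerow([f"{t:.4f}"])


def read_spike_times_csv(path) -> np.ndarray:
    import pandas as pd

    df = pd.read_csv(path)
    if df.empty:
        return np.empty(0)
    return df.iloc[:, 0].to_numpy(float)
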