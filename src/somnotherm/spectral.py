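"""Power spectral density estimation and band-power / delta-ratio statistics.

PSDs are Welch averages of Hann-windowed, 50 %-overlapped, mean-detrended
segment periodograms with one-sided density scaling, so that the integral of
the density over frequency equals the mean square of the (detrended) input
(Parseval contract).  The default segment length is 5 s — the vigilance
epoch — giving 0.2 Hz resolution; a 30 s analysis window then averages 11
overlapped segments.

Two delta-band conventions coexist deliberately and are never conflated:

* ``delta_display`` (0.5–4 Hz) — the band used for per-epoch classification
  features and the "virtual delta" channel;
* the delta *ratio* — band power 0.9–3.9 Hz divided by total power
  0.9–99 Hz.

Band membership uses the bin-center convention: a frequency bin belongs to a
band iff its center lies in the closed interval.  On the 0.2 Hz grid the
ratio's effective edges are therefore 1.0–3.8 Hz over 1.0–99.0 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .sigio import SignalRecording


@dataclass(frozen=True)
class SpectralBands:
    """Frequency bands (Hz) used by the analysis."""

    delta_display: tuple[float, float] = (0.5, 4.0)
    delta_ratio_numerator: tuple[float, float] = (0.9, 3.9)
    theta: tuple[float, float] = (4.0, 8.0)
    total: tuple[float, float] = (0.9, 99.0)

    def __post_init__(self):
        for lo, hi in (self.delta_display, self.delta_ratio_numerator, self.theta, self.total):
            if not lo < hi:
                raise ValueError(f"band ({lo}, {hi}) must have lo < hi")
        if not (self.total[0] <= self.delta_ratio_numerator[0]
                and self.delta_ratio_numerator[1] <= self.total[1]):
            raise ValueError("delta-ratio numerator band must lie inside the total band")


BANDS = SpectralBands()

#: Welch segment length, seconds (equals the scoring epoch)
DEFAULT_SEGMENT_S = 5.0


@dataclass
class PSDEstimate:
    """One-sided power spectral density, µV²/Hz on an even frequency grid."""

    freqs_hz: np.ndarray
    density: np.ndarray
    segment_length_s: float = DEFAULT_SEGMENT_S
    overlap_fraction: float = 0.5
    window_name: str = "hann"
    source_window: tuple[float, float] = (0.0, 0.0)  # (start_s, duration_s)

    def __post_init__(self):
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.freqs_hz.shape != self.density.shape:
            raise ValueError("freqs_hz and density must have equal length")
        if np.any(self.density < 0):
            raise ValueError("spectral density must be non-negative")

    @property
    def df(self) -> float:
        return float(self.freqs_hz[1] - self.freqs_hz[0])

    def total_power(self) -> float:
        """Integral of density over the full frequency axis, µV²."""
        return float(np.sum(self.density) * self.df)


def _welch(x: np.ndarray, fs: float, segment_s: float, overlap: float):
    nperseg = int(round(segment_s * fs))
    if len(x) < nperseg:
        raise ValueError(
            f"window of {len(x) / fs:g} s is shorter than one {segment_s:g} s segment"
        )
    noverlap = int(round(nperseg * overlap))
    freqs, pxx = sps.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap,
        detrend="constant", scaling="density", average="mean",
    )
    return freqs, pxx


def compute_psd(
    recording: SignalRecording,
    channel: str,
    window: tuple[float, float] | None = None,
    segment_length_s: float = DEFAULT_SEGMENT_S,
    overlap_fraction: float = 0.5,
) -> PSDEstimate:
    """Welch PSD of ``channel`` over ``window = (start_s, duration_s)``.

    Raises if the window falls outside the recording or is shorter than one
    segment.
    """
    fs = recording.sample_rate_hz
    x = recording.channel(channel)
    if window is None:
        window = (0.0, len(x) / fs)
    start_s, duration_s = window
    i0 = int(round(start_s * fs))
    i1 = int(round((start_s + duration_s) * fs))
    if start_s < 0 or i1 > len(x):
        raise ValueError(
            f"analysis window ({start_s:g} s, {duration_s:g} s) outside the "
            f"{len(x) / fs:g} s recording"
        )
    freqs, pxx = _welch(x[i0:i1], fs, segment_length_s, overlap_fraction)
    return PSDEstimate(freqs, pxx, segment_length_s, overlap_fraction, "hann",
                       (float(start_s), float(duration_s)))


def band_power(psd: PSDEstimate, lo_hz: float, hi_hz: float) -> float:
    """Band power (µV²): sum of density × bin width over bins with center in [lo, hi]."""
    if not lo_hz < hi_hz:
        raise ValueError("band must have lo < hi")
    nyquist = psd.freqs_hz[-1]
    mask = (psd.freqs_hz >= lo_hz) & (psd.freqs_hz <= hi_hz)
    if not mask.any():
        raise ValueError(
            f"band ({lo_hz}, {hi_hz}) Hz contains no frequency bins "
            f"(resolution {psd.df:g} Hz, Nyquist {nyquist:g} Hz)"
        )
    return float(np.sum(psd.density[mask]) * psd.df)


def delta_ratio(psd: PSDEstimate, bands: SpectralBands = BANDS) -> float:
    """Delta contribution to total power: P(0.9–3.9 Hz) / P(0.9–99 Hz)."""
    if psd.freqs_hz[-1] < bands.total[1]:
        raise ValueError(
            f"PSD reaches only {psd.freqs_hz[-1]:g} Hz; the total band needs "
            f"{bands.total[1]:g} Hz"
        )
    total = band_power(psd, *bands.total)
    if total <= 0:
        raise ValueError("total band power is zero; delta ratio undefined")
    return band_power(psd, *bands.delta_ratio_numerator) / total


def virtual_delta_channel(
    recording: SignalRecording,
    channel: str,
    step_s: float = 5.0,
    bands: SpectralBands = BANDS,
) -> np.ndarray:
    """Delta (0.5–4 Hz) band power in consecutive ``step_s`` windows.

    Emulates the acquisition software's "virtual delta" channel used to aid
    NREM identification: one band-power value per step, length
    ``floor(duration / step)``.
    """
    if step_s < 1.0:
        raise ValueError("step_s must be at least 1 s")
    fs = recording.sample_rate_hz
    x = recording.channel(channel)
    n_step = int(round(step_s * fs))
    n_out = len(x) // n_step
    if n_out == 0:
        raise ValueError("step_s exceeds the recording duration")
    out = np.empty(n_out)
    seg_s = min(DEFAULT_SEGMENT_S, step_s)
    for k in range(n_out):
        seg = x[k * n_step:(k + 1) * n_step]
        if not np.any(seg):
            out[k] = 0.0
            continue
        freqs, pxx = _welch(seg, fs, seg_s, 0.5)
        psd = PSDEstimate(freqs, pxx, seg_s, 0.5, "hann", (k * step_s, step_s))
        out[k] = band_power(psd, *bands.delta_display)
    return out


def export_psd_csv(psd: PSDEstimate, path) -> None:
    """Write ``freq_hz,density_uv2_per_hz`` plus a JSON parameter sidecar."""
    import json
    from pathlib import Path

    path = Path(path)
    with open(path, "w") as fh:
        fh.write("freq_hz,density_uv2_per_hz\n")
        for f, d in zip(psd.freqs_hz, psd.density):
            fh.write(f"{f:g},{d:.8g}\n")
    sidecar = {
        "segment_length_s": psd.segment_length_s,
        "overlap_fraction": psd.overlap_fraction,
        "window_name": psd.window_name,
        "source_window": list(psd.source_window),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
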