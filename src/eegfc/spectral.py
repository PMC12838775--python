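"""Band-limiting and instantaneous-phase extraction.

Signals are split into the four canonical EEG rhythms (delta 1-4 Hz, theta
4-8 Hz, alpha 8-13 Hz, beta 13-30 Hz) with a zero-phase Butterworth
band-pass, and the instantaneous phase of each band-limited channel is taken
as the angle of its analytic signal (Hilbert transform). Zero-phase
(forward-backward) filtering matters here because phase is the quantity the
rest of the pipeline measures: a causal filter would add a frequency-
dependent phase lag to every channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, hilbert, iirnotch, sosfiltfilt

from .recording import EEGRecording

__all__ = [
    "BandSpec",
    "DEFAULT_BANDS",
    "BandPhaseTensor",
    "bandpass",
    "notch",
    "broadband",
    "common_average",
    "instantaneous_phase",
    "decompose",
]


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError(f"invalid band edges ({self.f_lo}, {self.f_hi})")

    @property
    def center(self) -> float:
        return 0.5 * (self.f_lo + self.f_hi)

    def validate_for(self, fs: float) -> None:
        if self.f_hi >= fs / 2:
            raise ValueError(
                f"band {self.name} ({self.f_lo}-{self.f_hi} Hz) exceeds the "
                f"Nyquist frequency {fs / 2} Hz"
            )


DEFAULT_BANDS = [
    BandSpec("delta", 1.0, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 13.0),
    BandSpec("beta", 13.0, 30.0),
]


@dataclass
class BandPhaseTensor:
    """Per-channel instantaneous phase of one band.

    ``phases`` holds wrapped phases in (-pi, pi], one row per channel in the
    source recording's order. ``valid_range`` is the half-open sample range
    that survives edge trimming; every downstream phase-locking computation
    must restrict itself to it.
    """

    band: BandSpec
    fs: float
    channel_labels: list[str]
    phases: np.ndarray
    valid_range: tuple[int, int]

    @property
    def valid_phases(self) -> np.ndarray:
        """Phases restricted to the valid (edge-trimmed) sample range."""
        lo, hi = self.valid_range
        return self.phases[:, lo:hi]

    @property
    def n_valid(self) -> int:
        lo, hi = self.valid_range
        return hi - lo


def _butter_band(band: BandSpec, fs: float, order: int):
    band.validate_for(fs)
    return butter(order, [band.f_lo, band.f_hi], btype="bandpass", fs=fs, output="sos")


def bandpass(rec: EEGRecording, band: BandSpec, order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass of every channel.

    The filter is applied forward and backward (``sosfiltfilt``), so the
    output has no phase distortion and an effective order of ``2 * order``.
    """
    sos = _butter_band(band, rec.fs, order)
    padlen = 3 * (2 * sos.shape[0] + 1)
    if rec.n_samples <= padlen:
        raise ValueError(
            f"recording of {rec.n_samples} samples is shorter than the filter "
            f"warm-up ({padlen} samples)"
        )
    return rec.copy_with(sosfiltfilt(sos, rec.data, axis=1))


def broadband(rec: EEGRecording, f_lo: float = 0.5, f_hi: float = 45.0,
              order: int = 4) -> EEGRecording:
    """Optional broadband pre-filter (default 0.5-45 Hz), zero phase."""
    return bandpass(rec, BandSpec("broadband", f_lo, f_hi), order=order)


def notch(rec: EEGRecording, freq: float = 50.0, quality: float = 30.0) -> EEGRecording:
    """Optional zero-phase notch (default 50 Hz mains)."""
    if freq >= rec.fs / 2:
        raise ValueError("notch frequency above Nyquist")
    b, a = iirnotch(freq, quality, fs=rec.fs)
    return rec.copy_with(filtfilt(b, a, rec.data, axis=1))


def common_average(rec: EEGRecording) -> EEGRecording:
    """Optional common-average re-reference (subtract the channel mean)."""
    return rec.copy_with(rec.data - rec.data.mean(axis=0, keepdims=True))


def instantaneous_phase(signal: np.ndarray, fs: float | None = None) -> np.ndarray:
    """Instantaneous phase of a single-channel series via the analytic signal.

    Returns the four-quadrant angle of ``signal + i * HT(signal)``, wrapped to
    (-pi, pi]. For a pure sinusoid this is a linear phase ramp at the
    sinusoid's frequency.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("signal must be a 1-D series of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    if np.ptp(x) == 0:
        raise ValueError("constant signal has no defined instantaneous phase")
    phase = np.angle(hilbert(x))
    # np.angle returns [-pi, pi]; fold the closed lower endpoint onto +pi
    phase[phase == -np.pi] = np.pi
    return phase


def decompose(
    rec: EEGRecording,
    bands: list[BandSpec] | None = None,
    trim_s: float = 1.0,
    order: int = 4,
) -> list[BandPhaseTensor]:
    """Band-limit a recording and extract per-band phase tensors.

    ``trim_s`` seconds at each end are marked invalid to suppress filter and
    Hilbert edge transients; they are excluded from all downstream PLV
    computations via ``valid_range``.
    """
    if bands is None:
        bands = DEFAULT_BANDS
    trim = int(round(trim_s * rec.fs))
    if 2 * trim >= rec.n_samples:
        raise ValueError(
            f"trimming {trim_s} s per end leaves nothing of a "
            f"{rec.duration:.1f} s recording"
        )
    out = []
    for band in bands:
        filt = bandpass(rec, band, order=order)
        phases = np.empty_like(filt.data)
        for i in range(filt.n_channels):
            phases[i] = instantaneous_phase(filt.data[i])
        out.append(
            BandPhaseTensor(
                band=band,
                fs=rec.fs,
                channel_labels=list(rec.channel_labels),
                phases=phases,
                valid_range=(trim, rec.n_samples - trim),
            )
        )
    return out
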