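"""Multichannel EEG recording container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class EEGRecording:
    """A labeled multichannel time series.

    Parameters
    ----------
    channel_labels : list of str
        Ordered, unique electrode names. The default montage downstream is
        the eight 10-20 sites F3, F4, T3, C3, C4, T4, O1, O2.
    fs : float
        Sampling rate in Hz.
    data : ndarray, shape (n_channels, n_samples)
        Amplitudes in arbitrary units; every sample must be finite.
    subject_id : str
    group : str
        Cohort label (e.g. ``"TD"`` / ``"ASD"``); empty for ungrouped data.
    """

    channel_labels: list[str]
    fs: float
    data: np.ndarray
    subject_id: str = ""
    group: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) array")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray) -> "EEGRecording":
        """Return a copy of this recording carrying new sample data."""
        return EEGRecording(
            channel_labels=list(self.channel_labels),
            fs=self.fs,
            data=np.asarray(data, dtype=float),
            subject_id=self.subject_id,
            group=self.group,
            meta=dict(self.meta),
        )


DEFAULT_CHANNELS = ["F3", "F4", "T3", "C3", "C4", "T4", "O1", "O2"]
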