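import sys
import pathlib

import numpy as np
import pytest

sys.path.insert(0, str(pathlib.Path(__file__).parent))  # for oracles.py

from eegfc import DEFAULT_BANDS, EEGRecording, decompose


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


def make_sinusoid_recording(freqs, fs=250.0, duration=20.0, labels=None):
    """Recording whose channel i is a pure cosine at freqs[i] Hz."""
    t = np.arange(int(round(duration * fs))) / fs
    data = np.vstack([np.cos(2 * np.pi * f * t) for f in freqs])
    labels = labels or [f"ch{i}" for i in range(len(freqs))]
    return EEGRecording(labels, fs, data, subject_id="synthA")


@pytest.fixture(scope="session")
def alpha_recording():
    """Eight channels of 10 Hz cosines with staggered deterministic phases."""
    fs, duration = 250.0, 20.0
    t = np.arange(int(round(duration * fs))) / fs
    offsets = np.linspace(0, np.pi, 8, endpoint=False)
    data = np.vstack([np.cos(2 * np.pi * 10.0 * t + o) for o in offsets])
    labels = ["F3", "F4", "T3", "C3", "C4", "T4", "O1", "O2"]
    return EEGRecording(labels, fs, data, subject_id="alpha8")


@pytest.fixture(scope="session")
def alpha_tensors(alpha_recording):
    return decompose(alpha_recording, DEFAULT_BANDS, trim_s=1.0)


def random_symmetric_plv(rng, n, lo=0.05, hi=0.95):
    """Random symmetric matrix resembling a within-band PLV network."""
    A = rng.uniform(lo, hi, size=(n, n))
    W = 0.5 * (A + A.T)
    np.fill_diagonal(W, 1.0)
    return W


def random_weight_matrix(rng, n, density=0.8):
    """Random symmetric nonnegative weight matrix with zero diagonal."""
    A = rng.uniform(0.05, 1.0, size=(n, n))
    mask = rng.random((n, n)) < density
    A = A * mask
    W = 0.5 * (A + A.T)
    np.fill_diagonal(W, 0.0)
    return W
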