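"""Sliding-window dynamic networks, integration/segregation states, entropy.

The valid portion of each band's phase series is segmented into overlapping
windows (defaults: lengths 0.5, 1, 2, 4, 6, 8 s at 20% overlap) and a
connectivity matrix is computed per window, yielding a dynamic network
series. Each window's network is summarized by node-wise participation
coefficients over an anatomical module partition; K-means with k = 2
(best of 50 restarts) splits the windows into an integration state (dense
intermodular connectivity, labeled 1) and a segregation state (labeled 0).
The complexity of the resulting binary state sequence is the state entropy:
the Shannon entropy of the four consecutive-window pair types
(00, 01, 10, 11), normalized to [0, 1] by log 4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .connectivity import ConnectivityMatrix, cross_band_lofc, hofc, lofc
from .spectral import BandPhaseTensor

__all__ = [
    "WindowScheme",
    "DEFAULT_SCHEMES",
    "NetworkSeries",
    "Partition",
    "DEFAULT_PARTITION",
    "StateSequence",
    "window_slices",
    "dynamic_networks",
    "participation",
    "classify_states",
    "state_entropy",
]


@dataclass(frozen=True)
class WindowScheme:
    """Sliding-window geometry: length in seconds and overlap fraction."""

    length_s: float
    overlap_frac: float = 0.2

    def __post_init__(self) -> None:
        if self.length_s <= 0:
            raise ValueError("window length must be positive")
        if not 0 <= self.overlap_frac < 1:
            raise ValueError("overlap fraction must lie in [0, 1)")

    @property
    def step_s(self) -> float:
        return self.length_s * (1.0 - self.overlap_frac)


DEFAULT_SCHEMES = [WindowScheme(w, 0.2) for w in (0.5, 1.0, 2.0, 4.0, 6.0, 8.0)]

#: Default left/right anatomical module pairs of the 8-channel montage.
DEFAULT_PARTITION = {
    "F3": "frontal", "F4": "frontal",
    "C3": "central", "C4": "central",
    "T3": "temporal", "T4": "temporal",
    "O1": "occipital", "O2": "occipital",
}


@dataclass
class Partition:
    """Assignment of each node to one module; needs >= 2 modules."""

    modules: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.modules.values())) < 2:
            raise ValueError("partition needs at least 2 modules")

    def indicator(self, node_labels: list[str]) -> np.ndarray:
        """Integer module index per node, in node order."""
        missing = [n for n in node_labels if n not in self.modules]
        if missing:
            raise ValueError(f"nodes missing from partition: {missing}")
        names = sorted(set(self.modules[n] for n in node_labels))
        idx = {m: i for i, m in enumerate(names)}
        return np.array([idx[self.modules[n]] for n in node_labels])


@dataclass
class NetworkSeries:
    """Ordered per-window connectivity matrices of one band (or band pair)."""

    scheme: WindowScheme
    order: str
    matrices: list[ConnectivityMatrix]
    window_starts_s: np.ndarray

    def __len__(self) -> int:
        return len(self.matrices)


@dataclass
class StateSequence:
    """Binary integration (1) / segregation (0) labels, one per window."""

    labels: np.ndarray
    scheme: WindowScheme | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("state labels must be binary")


def window_slices(n_valid_samples: int, fs: float, scheme: WindowScheme) -> list[tuple[int, int]]:
    """Half-open [start, end) sample ranges of the sliding windows.

    The step is rounded to integer samples; a trailing partial window is
    dropped rather than padded, so every window's PLV averages the same
    number of samples.
    """
    win = int(round(scheme.length_s * fs))
    step = int(round(scheme.step_s * fs))
    if win > n_valid_samples:
        raise ValueError(
            f"window of {win} samples longer than the {n_valid_samples} valid samples"
        )
    if step < 1:
        raise ValueError("window step below one sample")
    count = (n_valid_samples - win) // step + 1
    return [(k * step, k * step + win) for k in range(count)]


def dynamic_networks(
    tensor: BandPhaseTensor,
    scheme: WindowScheme,
    order: str = "low",
    tensor_b: BandPhaseTensor | None = None,
    nm_ratio: tuple[int, int] | None = None,
) -> NetworkSeries:
    """Per-window connectivity series.

    ``order="low"`` computes a PLV network per window (within-band, or
    band-pair when ``tensor_b`` is given); ``order="high"`` additionally maps
    each window's low-order matrix through the high-order transform. Windows
    below roughly two cycles of the band's low edge give unstable PLV
    estimates; such schemes are used as configured but flagged with a warning.
    """
    if order not in ("low", "high"):
        raise ValueError("order must be 'low' or 'high'")
    if scheme.length_s * tensor.band.f_lo < 2:
        warnings.warn(
            f"window {scheme.length_s} s holds under two cycles of "
            f"{tensor.band.name} ({tensor.band.f_lo} Hz low edge); PLV "
            "estimates will be noisy",
            UserWarning,
            stacklevel=2,
        )
    lo, hi = tensor.valid_range
    slices = window_slices(hi - lo, tensor.fs, scheme)
    mats = []
    for (a, b) in slices:
        sub = _restrict(tensor, lo + a, lo + b)
        if tensor_b is None:
            M = lofc(sub)
        else:
            M = cross_band_lofc(sub, _restrict(tensor_b, lo + a, lo + b), nm_ratio)
        if order == "high":
            M = hofc(M)
        mats.append(M)
    starts = np.array([a / tensor.fs for a, _ in slices])
    return NetworkSeries(scheme=scheme, order=order, matrices=mats, window_starts_s=starts)


def _restrict(tensor: BandPhaseTensor, a: int, b: int) -> BandPhaseTensor:
    return BandPhaseTensor(
        band=tensor.band,
        fs=tensor.fs,
        channel_labels=tensor.channel_labels,
        phases=tensor.phases[:, a:b],
        valid_range=(0, b - a),
    )


def participation(W: np.ndarray, part: Partition, node_labels: list[str]) -> tuple[np.ndarray, float]:
    """Weighted participation coefficient per node, plus the network mean.

    PC_i = 1 - sum_s (kappa_is / k_i)^2 with kappa_is the strength of node i
    into module s and k_i its total strength; isolated nodes get PC_i = 0.
    """
    W = np.asarray(W, dtype=float)
    mod = part.indicator(node_labels)
    if W.shape[0] != mod.size:
        raise ValueError("partition does not match matrix size")
    k = W.sum(axis=1)
    n_mod = mod.max() + 1
    pc = np.zeros(W.shape[0])
    nz = k > 0
    frac_sq = np.zeros(W.shape[0])
    for s in range(n_mod):
        kappa = W[:, mod == s].sum(axis=1)
        frac_sq[nz] += (kappa[nz] / k[nz]) ** 2
    pc[nz] = 1.0 - frac_sq[nz]
    return pc, float(pc.mean())


def classify_states(
    features: np.ndarray,
    seed: int,
    k: int = 2,
    replicates: int = 50,
    scheme: WindowScheme | None = None,
) -> StateSequence:
    """K-means state labels of per-window participation features.

    ``features`` is windows x d (node-wise PC vectors, or a windows x 1
    column of network means). K-means with k = 2 and Euclidean distance is
    run ``replicates`` times from seeded random initializations, keeping the
    solution with the lowest within-cluster sum of squares; the cluster with
    the higher mean feature average (i.e. higher participation = denser
    intermodular connectivity) is labeled 1 = integration.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 windows to classify states")
    if np.unique(X, axis=0).shape[0] < 2:
        raise ValueError("all feature vectors identical; states are undefined")
    km = KMeans(n_clusters=k, n_init=replicates, random_state=seed)
    raw = km.fit_predict(X)
    # integration = the cluster with higher mean participation
    level = np.array([X[raw == c].mean() for c in range(k)])
    integration_cluster = int(np.argmax(level))
    labels = (raw == integration_cluster).astype(int)
    return StateSequence(labels=labels, scheme=scheme, meta={"inertia": float(km.inertia_)})


def state_entropy(seq: StateSequence | np.ndarray) -> float:
    """Normalized entropy of consecutive-window state pairs.

    The M = 4 pair types 00, 01, 10, 11 over consecutive windows get
    empirical probabilities p_i; SE = -(1/log M) * sum p_i log p_i with
    0 log 0 = 0. SE = 0 when a single pair type occurs (rigid dynamics) and
    SE = 1 when all four are equally frequent.
    """
    labels = seq.labels if isinstance(seq, StateSequence) else np.asarray(seq, dtype=int)
    if labels.size < 2:
        raise ValueError("need at least 2 state labels")
    pairs = 2 * labels[:-1] + labels[1:]
    counts = np.bincount(pairs, minlength=4).astype(float)
    p = counts / counts.sum()
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum() / np.log(4.0)) + 0.0
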