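"""Low-order, high-order and cross-frequency functional connectivity.

Low-order functional connectivity (LOFC) is the phase-locking value

    PLV = | (1/N) * sum_j exp(i * (phi_u[j] - phi_v[j])) |

between the instantaneous phases of two channels; it is 1 for a perfectly
constant phase relation and concentrates near sqrt(pi / (4 N)) for
independent phases.

High-order functional connectivity (HOFC) is a "correlation of
correlations": edge (i, j) is the Pearson correlation between the LOFC
connectivity profiles (columns) of nodes i and j, after removing the
self-connection rows i and j from both columns and applying Fisher's
z-transform (atanh) elementwise. It captures similarity of whole-network
connectivity patterns rather than direct pairwise synchrony.

Cross-frequency coupling is measured as the PLV between the phase series of
two different bands, for every ordered channel pair including the
same-channel case. The four within-band and six band-pair matrices assemble
into a supra-adjacency block matrix whose off-diagonal-block mean is the
global cross-band coordination metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .spectral import BandPhaseTensor, BandSpec

__all__ = [
    "ConnectivityMatrix",
    "SupraAdjacency",
    "DegenerateEdgeWarning",
    "plv",
    "plv_matrix",
    "lofc",
    "hofc",
    "cross_band_lofc",
    "assemble_supra",
    "cross_band_global",
]

ATANH_CLIP = 1.0 - 1e-12


class DegenerateEdgeWarning(UserWarning):
    """A reduced connectivity-profile column had zero variance; edge set to 0."""


@dataclass
class ConnectivityMatrix:
    """A square weighted functional network.

    ``order`` is ``"low"`` (PLV-based) or ``"high"`` (profile correlations).
    ``bands`` has one entry for a within-band network and two for a band-pair
    (cross-frequency) network. Conventions: within-band low-order matrices
    are symmetric in [0, 1] with unit diagonal; high-order matrices are
    symmetric in [-1, 1] with zero diagonal; band-pair low-order matrices are
    in [0, 1] and generally asymmetric (entry (i, j) couples channel i in the
    first band to channel j in the second). Diagonals are excluded from all
    graph metrics.
    """

    order: str
    bands: tuple[BandSpec, ...]
    node_labels: list[str]
    W: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.node_labels)
        if self.W.shape != (n, n):
            raise ValueError(f"matrix shape {self.W.shape} != ({n}, {n})")
        if self.order not in ("low", "high"):
            raise ValueError("order must be 'low' or 'high'")

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]

    @property
    def is_band_pair(self) -> bool:
        return len(self.bands) == 2

    @property
    def scope(self) -> str:
        if self.is_band_pair:
            return f"{self.bands[0].name}-{self.bands[1].name}"
        return self.bands[0].name


def plv(phase_u: np.ndarray, phase_v: np.ndarray) -> float:
    """Phase-locking value between two aligned phase series."""
    u = np.asarray(phase_u, dtype=float)
    v = np.asarray(phase_v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("phase series must be 1-D and of equal length")
    if u.size < 2:
        raise ValueError("need at least 2 samples")
    return float(abs(np.mean(np.exp(1j * (u - v)))))


def plv_matrix(phases: np.ndarray) -> np.ndarray:
    """All-pairs PLV of a (channels x samples) phase array, unit diagonal.

    Vectorized as the Gram matrix of unit phasors: PLV_ij = |<z_i, z_j>| / N
    for z = exp(i * phase).
    """
    z = np.exp(1j * np.asarray(phases, dtype=float))
    n = z.shape[1]
    if n < 2:
        raise ValueError("need at least 2 samples")
    M = np.abs(z @ z.conj().T) / n
    np.fill_diagonal(M, 1.0)
    return np.minimum(M, 1.0)


def lofc(tensor: BandPhaseTensor) -> ConnectivityMatrix:
    """Static within-band low-order network: all-pairs PLV over the valid range."""
    ph = tensor.valid_phases
    if ph.shape[0] < 2:
        raise ValueError("need at least 2 channels")
    return ConnectivityMatrix(
        order="low",
        bands=(tensor.band,),
        node_labels=list(tensor.channel_labels),
        W=plv_matrix(ph),
    )


def _hofc_weights(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    if n < 4:
        raise ValueError("high-order network needs >= 4 nodes")
    H = np.zeros((n, n))
    keep = np.arange(n)
    for i in range(n):
        for j in range(i + 1, n):
            mask = (keep != i) & (keep != j)
            ci = np.clip(W[mask, i], -ATANH_CLIP, ATANH_CLIP)
            cj = np.clip(W[mask, j], -ATANH_CLIP, ATANH_CLIP)
            zi = np.arctanh(ci)
            zj = np.arctanh(cj)
            si = zi.std()
            sj = zj.std()
            if si == 0.0 or sj == 0.0:
                warnings.warn(
                    f"zero-variance connectivity profile for edge ({i}, {j}); "
                    "high-order weight set to 0",
                    DegenerateEdgeWarning,
                    stacklevel=3,
                )
                r = 0.0
            else:
                r = float(np.corrcoef(zi, zj)[0, 1])
                # numerical guard: Pearson of finite data lies in [-1, 1]
                r = min(1.0, max(-1.0, r))
            H[i, j] = H[j, i] = r
    return H


def hofc(lofc_in: ConnectivityMatrix) -> ConnectivityMatrix:
    """High-order network from the column correlations of a low-order one.

    For each unordered node pair (i, j): take columns i and j of the weight
    matrix, delete rows i and j from both (removing the self-connection
    terms), Fisher-z-transform, and correlate. Columns with zero variance
    after row removal yield a 0 edge and a :class:`DegenerateEdgeWarning`
    rather than NaN, so downstream graph metrics stay defined.
    """
    if lofc_in.order != "low":
        raise ValueError("high-order networks are built from low-order input")
    return ConnectivityMatrix(
        order="high",
        bands=lofc_in.bands,
        node_labels=list(lofc_in.node_labels),
        W=_hofc_weights(lofc_in.W),
        meta={"source_scope": lofc_in.scope},
    )


def cross_band_lofc(
    tensor_a: BandPhaseTensor,
    tensor_b: BandPhaseTensor,
    nm_ratio: tuple[int, int] | None = None,
) -> ConnectivityMatrix:
    """Between-frequency low-order network.

    Entry (i, j) is the PLV between channel i's phase in band a and channel
    j's phase in band b, for every ordered pair including i = j. By default
    the literal 1:1 phase difference is used. With ``nm_ratio = (n, m)`` the
    generalized n:m locking value |mean exp(i*(n*phi_a - m*phi_b))| is
    computed instead, which is the stationary statistic when the two rhythms
    are harmonically related (n * f_a ~= m * f_b).
    """
    if tensor_a.channel_labels != tensor_b.channel_labels:
        raise ValueError("cross-band tensors must share channels")
    if tensor_a.valid_range != tensor_b.valid_range or tensor_a.fs != tensor_b.fs:
        raise ValueError("cross-band tensors must share sampling and valid range")
    if tensor_a.band == tensor_b.band:
        raise ValueError("cross-band PLV needs two distinct bands")
    n, m = (1, 1) if nm_ratio is None else nm_ratio
    za = np.exp(1j * n * tensor_a.valid_phases)
    zb = np.exp(1j * m * tensor_b.valid_phases)
    N = za.shape[1]
    W = np.abs(za @ zb.conj().T) / N
    return ConnectivityMatrix(
        order="low",
        bands=(tensor_a.band, tensor_b.band),
        node_labels=list(tensor_a.channel_labels),
        W=np.minimum(W, 1.0),
        meta={"nm_ratio": (n, m)},
    )


@dataclass
class SupraAdjacency:
    """Multiband supra-adjacency block matrix.

    For B bands and C channels, S is (B*C) x (B*C): diagonal blocks are the
    within-band low-order networks and off-diagonal block (a, b) holds the
    band-pair matrix for (band_a, band_b), with block (b, a) its transpose so
    S is symmetric by construction.
    """

    bands: tuple[BandSpec, ...]
    node_labels: list[str]
    S: np.ndarray

    @property
    def n_channels(self) -> int:
        return len(self.node_labels)

    def block(self, a: int, b: int) -> np.ndarray:
        C = self.n_channels
        return self.S[a * C:(a + 1) * C, b * C:(b + 1) * C]

    @property
    def supra_labels(self) -> list[str]:
        return [f"{band.name}:{ch}" for band in self.bands for ch in self.node_labels]


def assemble_supra(
    within: list[ConnectivityMatrix],
    between: list[ConnectivityMatrix],
) -> SupraAdjacency:
    """Assemble within-band and band-pair matrices into a supra-adjacency."""
    if not within:
        raise ValueError("need at least one within-band matrix")
    bands = tuple(M.bands[0] for M in within)
    labels = list(within[0].node_labels)
    C = len(labels)
    B = len(bands)
    for M in within:
        if M.is_band_pair or M.node_labels != labels:
            raise ValueError("within blocks must be within-band with shared labels")
    pair_map = {}
    for M in between:
        if not M.is_band_pair or M.node_labels != labels:
            raise ValueError("between blocks must be band-pair with shared labels")
        pair_map[(M.bands[0].name, M.bands[1].name)] = M.W
    S = np.zeros((B * C, B * C))
    for a in range(B):
        S[a * C:(a + 1) * C, a * C:(a + 1) * C] = within[a].W
        for b in range(a + 1, B):
            key = (bands[a].name, bands[b].name)
            rkey = (bands[b].name, bands[a].name)
            if key in pair_map:
                blk = pair_map[key]
            elif rkey in pair_map:
                blk = pair_map[rkey].T
            else:
                raise ValueError(f"missing band-pair block {key}")
            S[a * C:(a + 1) * C, b * C:(b + 1) * C] = blk
            S[b * C:(b + 1) * C, a * C:(a + 1) * C] = blk.T
    return SupraAdjacency(bands=bands, node_labels=labels, S=S)


def cross_band_global(supra: SupraAdjacency) -> tuple[dict[tuple[str, str], float], float]:
    """Per-pair block means and the overall cross-band global metric.

    For each unordered band pair, the arithmetic mean of that block's C^2
    entries; the overall metric is the mean over all off-diagonal-block
    entries (identical to the mean of the per-pair means, since all blocks
    share the same size).
    """
    B = len(supra.bands)
    per_pair: dict[tuple[str, str], float] = {}
    total = 0.0
    count = 0
    for a in range(B):
        for b in range(a + 1, B):
            blk = supra.block(a, b)
            per_pair[(supra.bands[a].name, supra.bands[b].name)] = float(blk.mean())
            total += blk.sum()
            count += blk.size
    overall = total / count if count else float("nan")
    return per_pair, float(overall)
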