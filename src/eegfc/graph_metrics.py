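"""Weighted graph-theory metrics: CC, CPL, GE, LE.

All four metrics follow the standard weighted-network formulations for
undirected graphs with weights in [0, 1] (Rubinov-Sporns style):

* clustering coefficient (CC): mean over nodes of the geometric-mean
  triangle intensity, sum_{j,h} (w_ij w_ih w_jh)^(1/3) / (k_i (k_i - 1)),
  with k_i the binary degree; nodes of degree < 2 contribute 0;
* characteristic path length (CPL): mean shortest-path distance over
  ordered node pairs, on connection lengths l_ij = 1 / w_ij (w = 0 means no
  edge); any unreachable pair makes CPL infinite, and the finite-pair mean
  is reported alongside as a fallback;
* global efficiency (GE): mean of 1 / d_ij over ordered pairs, with
  1 / inf = 0, so disconnected graphs are handled natively;
* local efficiency (LE): mean over nodes of the efficiency of the node's
  neighborhood subgraph, with cube-root weight terms
  (w_ij w_ih [d_jh(N_i)]^(-1))^(1/3), where d_jh(N_i) is the shortest path
  between neighbors j, h restricted to N_i and computed on cube-root
  lengths; nodes with < 2 neighbors contribute 0.

No thresholding or binarization is applied: metrics are computed on the
original continuous weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import dijkstra

from .connectivity import ConnectivityMatrix

__all__ = [
    "LengthMatrix",
    "GraphMetricSet",
    "prepare_weights",
    "shortest_paths",
    "clustering_coefficient",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "metric_set",
]


@dataclass
class LengthMatrix:
    """All-pairs shortest-path distances (dimensionless; +inf = unreachable)."""

    node_labels: list[str]
    D: np.ndarray


@dataclass
class GraphMetricSet:
    """The four topological metrics of one network, plus provenance."""

    cc: float
    cpl: float
    ge: float
    le: float
    cpl_finite: float = float("nan")
    disconnected: bool = False
    meta: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"cc": self.cc, "cpl": self.cpl, "ge": self.ge, "le": self.le}


def prepare_weights(M: ConnectivityMatrix | np.ndarray, mode: str = "clip") -> np.ndarray:
    """Map a connectivity matrix to nonnegative graph weights.

    Low-order (PLV) weights already lie in [0, 1] and pass through
    unchanged. High-order weights can be negative; ``mode="clip"`` (default)
    sets negatives to 0, ``mode="absolute"`` takes |w|. The diagonal is
    always zeroed: self-connections never enter the metrics.
    """
    if isinstance(M, ConnectivityMatrix):
        W = M.W.copy()
    else:
        W = np.asarray(M, dtype=float).copy()
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(W, W.T, atol=1e-12):
        raise ValueError("weight matrix must be symmetric")
    W = 0.5 * (W + W.T)  # remove residual float asymmetry
    np.fill_diagonal(W, 0.0)
    if mode == "clip":
        W = np.where(W < 0, 0.0, W)
    elif mode == "absolute":
        W = np.abs(W)
    else:
        raise ValueError(f"unknown weight-preparation mode {mode!r}")
    return W


def _length_from_weight(W: np.ndarray, mapping: str = "inverse") -> np.ndarray:
    with np.errstate(divide="ignore"):
        if mapping == "inverse":
            L = 1.0 / W
        elif mapping == "neglog":
            L = -np.log(W)
        else:
            raise ValueError(f"unknown weight-to-length mapping {mapping!r}")
    L[W == 0] = np.inf
    return L


def _dijkstra_all(L: np.ndarray) -> np.ndarray:
    finite = np.where(np.isfinite(L), L, 0.0)
    D = dijkstra(finite, directed=False, unweighted=False)
    np.fill_diagonal(D, 0.0)
    return D


def shortest_paths(W: np.ndarray, mapping: str = "inverse") -> LengthMatrix:
    """All-pairs shortest paths on lengths l = 1/w (or -log w)."""
    W = np.asarray(W, dtype=float)
    D = _dijkstra_all(_length_from_weight(W, mapping))
    labels = [str(i) for i in range(W.shape[0])]
    return LengthMatrix(node_labels=labels, D=D)


def clustering_coefficient(W: np.ndarray) -> float:
    """Mean weighted clustering coefficient (geometric-mean triangles)."""
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    Wr = np.cbrt(W)
    cyc3 = np.diag(Wr @ Wr @ Wr)  # sum over j,h of (w_ij w_jh w_hi)^(1/3)
    k = (W > 0).sum(axis=1)
    cc = np.zeros(n)
    has = k >= 2
    cc[has] = cyc3[has] / (k[has] * (k[has] - 1))
    return float(cc.mean()) if n else 0.0


def characteristic_path_length(D: LengthMatrix | np.ndarray) -> tuple[float, float, bool]:
    """Mean shortest-path length over ordered pairs.

    Returns ``(cpl, cpl_finite, disconnected)``: if any pair is unreachable,
    ``cpl`` is +inf, ``disconnected`` is True, and ``cpl_finite`` is the mean
    over reachable pairs only (NaN when no pair is reachable).
    """
    Dm = D.D if isinstance(D, LengthMatrix) else np.asarray(D, dtype=float)
    n = Dm.shape[0]
    if n < 2:
        return float("nan"), float("nan"), False
    off = ~np.eye(n, dtype=bool)
    vals = Dm[off]
    finite = np.isfinite(vals)
    cpl_finite = float(vals[finite].mean()) if finite.any() else float("nan")
    if finite.all():
        return cpl_finite, cpl_finite, False
    return float("inf"), cpl_finite, True


def global_efficiency(D: LengthMatrix | np.ndarray) -> float:
    """Mean inverse shortest-path length over ordered pairs (1/inf = 0)."""
    Dm = D.D if isinstance(D, LengthMatrix) else np.asarray(D, dtype=float)
    n = Dm.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / Dm[off]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def local_efficiency(W: np.ndarray) -> float:
    """Mean weighted local efficiency over nodes.

    For each node u with neighborhood N(u): shortest paths among the
    neighbors are computed on the subgraph restricted to N(u) with cube-root
    lengths (1/w)^(1/3); the node's efficiency averages the cube-root terms
    (w_uj w_uh / d_jh)^(1/3) over ordered neighbor pairs, normalized by
    k_u (k_u - 1). Nodes with < 2 neighbors contribute 0.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if n == 0:
        return 0.0
    eloc = np.zeros(n)
    for u in range(n):
        nbrs = np.flatnonzero(W[u] > 0)
        k = nbrs.size
        if k < 2:
            continue
        sub = W[np.ix_(nbrs, nbrs)]
        Lsub = _length_from_weight(np.cbrt(sub))
        Dsub = _dijkstra_all(Lsub)
        with np.errstate(divide="ignore"):
            e = 1.0 / Dsub
        e[~np.isfinite(e)] = 0.0
        np.fill_diagonal(e, 0.0)
        sw = np.cbrt(W[u, nbrs])
        numer = float((np.outer(sw, sw) * e).sum())
        eloc[u] = numer / (k * (k - 1))
    return float(eloc.mean())


def metric_set(
    M: ConnectivityMatrix | np.ndarray,
    mode: str = "clip",
    mapping: str = "inverse",
) -> GraphMetricSet:
    """Compute all four metrics of a network after weight preparation."""
    W = prepare_weights(M, mode=mode)
    D = shortest_paths(W, mapping=mapping)
    cpl, cpl_finite, disconnected = characteristic_path_length(D)
    meta = {"weight_mode": mode, "length_mapping": mapping}
    if isinstance(M, ConnectivityMatrix):
        meta.update(order=M.order, scope=M.scope)
    return GraphMetricSet(
        cc=clustering_coefficient(W),
        cpl=cpl,
        ge=global_efficiency(D),
        le=local_efficiency(W),
        cpl_finite=cpl_finite,
        disconnected=disconnected,
        meta=meta,
    )
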