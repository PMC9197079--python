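"""Structural-connectivity normalization and hybrid local/distant weighting.

A raw streamline-weight matrix is log-transformed and min-max scaled to [0, 1]
(`normalize_sc`). The hybrid connectivity A assigns weight 1 to voxel pairs in
the same parcellation node and λ·SC_ab to pairs in different nodes a, b; λ can
be estimated from the variance of a track-density image, which proxies the
quality of the diffusion data and hence the reliability of the connectome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ConnectomeMatrix, Volume3D

__all__ = [
    "HybridConnectivity",
    "normalize_sc",
    "hybrid_weight",
    "estimate_lambda",
]


def normalize_sc(raw: ConnectomeMatrix) -> ConnectomeMatrix:
    """Log-transform and min-max scale a raw connectivity matrix to [0, 1].

    Entries map as v' = (log10(1+v) - min) / (max - min), with min and max
    taken over all off-diagonal entries (zeros included), so an absent edge
    normalizes to 0 and the strongest edge to 1. The +1 offset keeps
    zero-streamline edges finite and maps "no connection" to 0. The diagonal
    is set to 0: same-node smoothing is carried by the local term, never by
    the SC matrix. If all off-diagonal entries are equal, positive entries
    map to 1 and zeros to 0.
    """
    if raw.normalized:
        raise ValueError("connectome is already normalized")
    n = raw.n_nodes
    logv = np.log10(1.0 + raw.values)
    off = ~np.eye(n, dtype=bool)
    out = np.zeros_like(logv)
    if n > 1:
        lo = logv[off].min()
        hi = logv[off].max()
        if hi > lo:
            out[off] = (logv[off] - lo) / (hi - lo)
        else:
            out[off] = (raw.values[off] > 0).astype(np.float64)
    return ConnectomeMatrix(values=out, node_ids=list(raw.node_ids), normalized=True)


@dataclass
class HybridConnectivity:
    """Hybrid local/distant connectivity A over parcellation nodes.

    A(a, a) = 1 for any node a (local connectivity is uniform), and
    A(a, b) = λ·SC_ab for distinct nodes a ≠ b. Label 0 (outside the
    parcellation) behaves as its own local class: weight 1 with other label-0
    voxels, 0 with every parcellated node — the filter then smooths
    non-parcellated tissue among itself without inventing distant edges.
    """

    sc_norm: ConnectomeMatrix
    lam: float
    local_value: float = 1.0

    def __post_init__(self) -> None:
        if not self.sc_norm.normalized:
            raise ValueError("HybridConnectivity requires a normalized SC matrix")
        if self.lam < 0:
            raise ValueError("lam must be non-negative")
        self.lam = float(self.lam)

    def weight(self, node_a: int, node_b: int) -> float:
        """Hybrid weight A for a pair of node labels (0 = outside parcellation)."""
        node_a, node_b = int(node_a), int(node_b)
        for node in (node_a, node_b):
            if node > 0 and node not in self.sc_norm.node_ids:
                raise KeyError(f"unknown node id {node}")
        if node_a == node_b:
            return self.local_value
        if node_a == 0 or node_b == 0:
            return 0.0
        ia = self.sc_norm.index_of(node_a)
        ib = self.sc_norm.index_of(node_b)
        return self.lam * float(self.sc_norm.values[ia, ib])

    def lookup_table(self, labels: list[int]) -> np.ndarray:
        """Dense A table over the given label list (0 allowed), in list order."""
        k = len(labels)
        table = np.empty((k, k), dtype=np.float64)
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                table[i, j] = self.weight(a, b)
        return table


def hybrid_weight(H: HybridConnectivity, node_a: int, node_b: int) -> float:
    """Functional form of :meth:`HybridConnectivity.weight`."""
    return H.weight(node_a, node_b)


def estimate_lambda(tdi: Volume3D, B: float) -> float:
    """Connectivity ratio λ = B · σ²(TDI) from track-density image variance.

    The TDI variance (sample variance, over the volume's mask) rises with
    diffusion data quality and tracking fidelity, so λ gives distant
    connectivity more weight when the connectome is trustworthy.
    """
    if B <= 0:
        raise ValueError("B must be positive")
    if tdi.mask is None:
        raise ValueError("TDI volume must carry a mask defining the variance region")
    vals = tdi.data[tdi.mask]
    if vals.size < 2:
        raise ValueError("need at least 2 masked TDI voxels to compute a variance")
    return float(B * np.var(vals, ddof=1))
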