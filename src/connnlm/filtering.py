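"""Non-local means filtering with hybrid connectome weighting.

The filter replaces every masked voxel intensity x_i by a weighted average of
all masked voxels x_j in the search window. The weight of pair (i, j) is

    w'_ij ∝ exp(-||p_i - p_j||²_{2,a} / h²) · A_ij

where p_i is the 2D axial patch around i, ||·||_{2,a} the Euclidean patch
distance weighted by a Gaussian kernel of std ``a`` (the centre voxel counts
more than the rim), h² the smoothing strength, and A_ij the hybrid
connectivity: 1 for voxels in the same parcellation node, λ·SC_ab across
nodes. Weights are normalized to sum to one at every voxel, so the output is
a convex combination of masked input intensities.

Patches are 2D (in-slice) while the search window is 3D; by default the
window is the whole volume. The production path factorizes the pairwise patch
distances through a Gram matrix and processes target voxels in chunks; the
result is a pure function of the inputs, independent of chunking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .connectivity import HybridConnectivity
from .io import FilterParams, ParcellationVolume, Volume3D

__all__ = [
    "PatchKernel",
    "WeightField",
    "gaussian_patch_kernel",
    "extract_patch",
    "patch_distance",
    "similarity_weight",
    "conn_nlm_filter",
    "conn_nlm_oracle",
    "nlm_filter",
    "gaussian_baseline",
    "tv_baseline",
    "estimate_h2",
    "weight_field",
]

_ORACLE_MAX_VOXELS = 4096


@dataclass
class PatchKernel:
    """2D Gaussian weighting of the patch distance, normalized to sum 1."""

    size: int
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.size % 2 == 0 or self.size < 1:
            raise ValueError("patch kernel size must be odd and >= 1")
        if self.weights.shape != (self.size, self.size):
            raise ValueError("kernel weights must be size x size")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("kernel weights must sum to 1")


@dataclass
class WeightField:
    """Contributing voxels and normalized weights for one target voxel."""

    center: tuple[int, int, int]
    indices: np.ndarray  # (n, 3) voxel coordinates, includes the center
    weights: np.ndarray  # (n,) non-negative, sums to 1 within 1e-9


def gaussian_patch_kernel(size: int, a: float) -> PatchKernel:
    """Build the 2D Gaussian patch kernel of std ``a`` voxels, sum-normalized."""
    if size % 2 == 0 or size < 1:
        raise ValueError(f"patch size must be odd and >= 1, got {size}")
    if a <= 0:
        raise ValueError("kernel std a must be positive")
    r = size // 2
    coords = np.arange(-r, r + 1, dtype=np.float64)
    g1 = np.exp(-(coords**2) / (2.0 * a * a))
    g2 = np.outer(g1, g1)
    return PatchKernel(size=size, weights=g2 / g2.sum())


def _reflect_indices(n: int, r: int) -> np.ndarray:
    """Mirror-boundary index map of length n + 2r into [0, n)."""
    idx = np.arange(-r, n + r)
    if n == 1:
        return np.zeros_like(idx)
    period = 2 * n - 2
    idx = np.mod(idx, period)
    return np.where(idx >= n, period - idx, idx)


def _padded_inplane(data: np.ndarray, r: int) -> np.ndarray:
    """Reflect-pad the first two (in-plane) axes by r voxels."""
    if r == 0:
        return data
    xi = _reflect_indices(data.shape[0], r)
    yi = _reflect_indices(data.shape[1], r)
    return data[np.ix_(xi, yi, np.arange(data.shape[2]))]


def extract_patch(vol: Volume3D, center: tuple[int, int, int], M: int) -> np.ndarray:
    """The axial M×M intensity patch around ``center``, reflect-padded at borders."""
    if M % 2 == 0 or M < 1:
        raise ValueError(f"patch size must be odd, got {M}")
    x, y, z = (int(c) for c in center)
    nx, ny, nz = vol.shape
    if not (0 <= x < nx and 0 <= y < ny and 0 <= z < nz):
        raise IndexError(f"center {center} outside volume of shape {vol.shape}")
    r = M // 2
    xi = _reflect_indices(nx, r)[x : x + M]
    yi = _reflect_indices(ny, r)[y : y + M]
    return vol.data[np.ix_(xi, yi, [z])][:, :, 0]


def patch_distance(p_i: np.ndarray, p_j: np.ndarray, kernel: PatchKernel) -> float:
    """Gaussian-weighted squared Euclidean distance between two patches."""
    p_i = np.asarray(p_i, dtype=np.float64)
    p_j = np.asarray(p_j, dtype=np.float64)
    if p_i.shape != p_j.shape or p_i.shape != kernel.weights.shape:
        raise ValueError(
            f"patch shapes {p_i.shape}, {p_j.shape} must match kernel {kernel.weights.shape}"
        )
    diff = p_i - p_j
    return float(np.sum(kernel.weights * diff * diff))


def similarity_weight(d: float, h2: float) -> float:
    """Intensity similarity weight exp(-d / h²) in (0, 1]."""
    if h2 <= 0:
        raise ValueError("h2 must be strictly positive")
    return float(np.exp(-d / h2))


def estimate_h2(pet: Volume3D, noise_mask: np.ndarray, C: float) -> float:
    """Smoothing strength h² = C · σ²(PET) from a background-noise region.

    σ² is the sample variance of the voxel values under ``noise_mask``; the
    noisier the image, the stronger the filtering. A constant region yields
    h² = 0, which the filters reject — pick a region that actually contains
    noise.
    """
    if C <= 0:
        raise ValueError("C must be positive")
    noise_mask = np.asarray(noise_mask, dtype=bool)
    if noise_mask.shape != pet.shape:
        raise ValueError("noise mask shape must match volume")
    vals = pet.data[noise_mask]
    if vals.size < 2:
        raise ValueError("need at least 2 voxels in the noise mask")
    return float(C * np.var(vals, ddof=1))


# ---------------------------------------------------------------------------
# Filter engine


def _patch_feature_volume(data: np.ndarray, M: int, kernel: PatchKernel) -> np.ndarray:
    """Per-voxel patch feature vectors scaled by sqrt(kernel weights).

    Squared Euclidean distance between two feature rows equals the
    Gaussian-weighted patch distance of the corresponding voxels.
    """
    nx, ny, nz = data.shape
    r = M // 2
    padded = _padded_inplane(data, r)
    sqrt_g = np.sqrt(kernel.weights)
    F = np.empty((nx, ny, nz, M * M), dtype=np.float64)
    k = 0
    for dx in range(M):
        for dy in range(M):
            F[..., k] = padded[dx : dx + nx, dy : dy + ny, :] * sqrt_g[dx, dy]
            k += 1
    return F


def _window_radii(params: FilterParams) -> tuple[int, int]:
    """(in-plane radius, slice radius); (-1, -1) means whole volume."""
    if params.window == "whole_volume":
        return -1, -1
    n, s = params.window
    return n // 2, max(0, (s - 1) // 2)


def _validate_inputs(pet: Volume3D, parc: ParcellationVolume | None,
                     H: HybridConnectivity | None) -> np.ndarray:
    mask = pet.effective_mask()
    if not mask.any():
        raise ValueError("empty mask: nothing to filter")
    if parc is not None:
        if parc.shape != pet.shape:
            raise ValueError(f"parcellation shape {parc.shape} != volume shape {pet.shape}")
        if H is not None:
            missing = set(parc.node_ids) - set(H.sc_norm.node_ids)
            if missing:
                raise ValueError(
                    f"parcellation labels {sorted(missing)} absent from connectome"
                )
    return mask


def _label_table(parc: ParcellationVolume | None, H: HybridConnectivity | None,
                 shape: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Map voxels to compact class indices and build the dense A table.

    Class 0 is the out-of-parcellation label 0; classes 1..K are the node ids
    present in the connectome. With no parcellation (plain NLM) every voxel is
    one class with A ≡ 1.
    """
    if parc is None or H is None:
        return np.zeros(shape, dtype=np.int64), np.ones((1, 1), dtype=np.float64)
    labels = [0] + list(H.sc_norm.node_ids)
    lut = np.zeros(max(labels) + 1, dtype=np.int64)
    for ci, lab in enumerate(labels):
        lut[lab] = ci
    node_idx = lut[parc.labels]
    table = H.lookup_table(labels)
    return node_idx, table


def _filter_whole_volume(data, mask, node_idx_vol, Atable, params, kernel,
                         max_chunk_bytes: int = 256 << 20) -> np.ndarray:
    F_vol = _patch_feature_volume(data, params.patch_size, kernel)
    F = F_vol[mask]
    vals = data[mask]
    ni = node_idx_vol[mask]
    n = F.shape[0]
    sq = np.einsum("ij,ij->i", F, F)
    A_cols = Atable[:, ni]  # (K, n): per-class weight against every source voxel
    out_vals = np.empty(n, dtype=np.float64)
    chunk = max(8, min(n, max_chunk_bytes // (8 * max(n, 1))))
    inv_h2 = 1.0 / params.h2
    for s in range(0, n, chunk):
        e = min(s + chunk, n)
        G = F[s:e] @ F.T
        G *= -2.0
        G += sq[s:e, None]
        G += sq[None, :]
        np.maximum(G, 0.0, out=G)  # clamp Gram-expansion cancellation
        G *= -inv_h2
        W = np.exp(G, out=G)
        W *= A_cols[ni[s:e]]
        Z = W.sum(axis=1)
        out_vals[s:e] = (W @ vals) / Z
    out = data.copy()
    out[mask] = out_vals
    return out


def _filter_windowed(data, mask, node_idx_vol, Atable, params, kernel) -> np.ndarray:
    wr, sr = _window_radii(params)
    F_vol = _patch_feature_volume(data, params.patch_size, kernel)
    out = data.copy()
    inv_h2 = 1.0 / params.h2
    nx, ny, nz = data.shape
    for x, y, z in np.argwhere(mask):
        xs = slice(max(0, x - wr), min(nx, x + wr + 1))
        ys = slice(max(0, y - wr), min(ny, y + wr + 1))
        zs = slice(max(0, z - sr), min(nz, z + sr + 1))
        sub = mask[xs, ys, zs]
        Fj = F_vol[xs, ys, zs][sub]
        d = Fj - F_vol[x, y, z]
        d = np.einsum("ij,ij->i", d, d)
        w = np.exp(-d * inv_h2)
        w *= Atable[node_idx_vol[x, y, z], node_idx_vol[xs, ys, zs][sub]]
        out[x, y, z] = (w @ data[xs, ys, zs][sub]) / w.sum()
    return out


def _run_filter(pet: Volume3D, parc: ParcellationVolume | None,
                H: HybridConnectivity | None, params: FilterParams) -> Volume3D:
    mask = _validate_inputs(pet, parc, H)
    node_idx, Atable = _label_table(parc, H, pet.shape)
    kernel = gaussian_patch_kernel(params.patch_size, params.a)
    if params.window == "whole_volume":
        out = _filter_whole_volume(pet.data, mask, node_idx, Atable, params, kernel)
    else:
        out = _filter_windowed(pet.data, mask, node_idx, Atable, params, kernel)
    return pet.with_data(out)


def weight_field(pet: Volume3D, parc: ParcellationVolume | None,
                 H: HybridConnectivity | None, params: FilterParams,
                 center: tuple[int, int, int]) -> WeightField:
    """Normalized combined weights w'_ij of every contributing voxel j for one i."""
    mask = _validate_inputs(pet, parc, H)
    x, y, z = (int(c) for c in center)
    if not mask[x, y, z]:
        raise ValueError(f"center {center} is outside the mask")
    node_idx, Atable = _label_table(parc, H, pet.shape)
    kernel = gaussian_patch_kernel(params.patch_size, params.a)
    F_vol = _patch_feature_volume(pet.data, params.patch_size, kernel)
    wr, sr = _window_radii(params)
    nx, ny, nz = pet.shape
    if wr < 0:
        region = mask
    else:
        region = np.zeros_like(mask)
        xs = slice(max(0, x - wr), min(nx, x + wr + 1))
        ys = slice(max(0, y - wr), min(ny, y + wr + 1))
        zs = slice(max(0, z - sr), min(nz, z + sr + 1))
        region[xs, ys, zs] = mask[xs, ys, zs]
    idx = np.argwhere(region)
    Fj = F_vol[region]
    d = Fj - F_vol[x, y, z]
    d = np.einsum("ij,ij->i", d, d)
    w = np.exp(-d / params.h2)
    w *= Atable[node_idx[x, y, z], node_idx[region]]
    w /= w.sum()
    return WeightField(center=(x, y, z), indices=idx, weights=w)


def conn_nlm_filter(pet: Volume3D, parc: ParcellationVolume,
                    H: HybridConnectivity, params: FilterParams) -> Volume3D:
    """Connectome-weighted non-local means filtering of a PET volume.

    Every masked voxel becomes the w'-weighted average of all masked voxels in
    the search window; voxels outside the mask are copied unchanged. The
    normalizer is always positive since j = i contributes weight 1·A_local.
    The connectivity ratio is taken from ``H.lam`` (the hybrid weighting is
    authoritative); ``params.lam`` is not consulted here.
    """
    from .denoisers import ConnNLMDenoiser

    est = ConnNLMDenoiser(
        h2=params.h2, a=params.a, patch_size=params.patch_size,
        window=params.window, lam=H.lam,
    )
    est.fit(pet, parcellation=parc, connectome=H.sc_norm)
    return est.transform(pet)


def nlm_filter(pet: Volume3D, params: FilterParams) -> Volume3D:
    """Plain non-local means: the connectome-weighted filter with A_ij ≡ 1."""
    from .denoisers import NLMDenoiser

    est = NLMDenoiser(
        h2=params.h2, a=params.a, patch_size=params.patch_size, window=params.window
    )
    est.fit(pet)
    return est.transform(pet)


def gaussian_baseline(pet: Volume3D, fwhm_voxels: float) -> Volume3D:
    """3D Gaussian smoothing baseline (reflect boundary), FWHM in voxels."""
    from .denoisers import GaussianDenoiser

    return GaussianDenoiser(fwhm=fwhm_voxels).fit(pet).transform(pet)


def tv_baseline(pet: Volume3D, weight: float, iters: int = 200) -> Volume3D:
    """Total-variation (ROF-type) denoising baseline; deterministic."""
    from .denoisers import TVDenoiser

    return TVDenoiser(weight=weight, n_iter=iters).fit(pet).transform(pet)


# ---------------------------------------------------------------------------
# Brute-force reference oracle: literal loops over target voxel, source voxel
# and patch element. Restricted to tiny volumes; used to validate the
# production path, never as the production path.


@njit(cache=False)
def _oracle_loops(padded, data, mask, node_idx, Atable, g, h2, wr, sr, out):  # pragma: no cover
    nx, ny, nz = data.shape
    M = g.shape[0]
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                num = 0.0
                den = 0.0
                for jx in range(nx):
                    for jy in range(ny):
                        for jz in range(nz):
                            if not mask[jx, jy, jz]:
                                continue
                            if wr >= 0:
                                if abs(jx - x) > wr or abs(jy - y) > wr or abs(jz - z) > sr:
                                    continue
                            d = 0.0
                            for u in range(M):
                                for v in range(M):
                                    diff = padded[x + u, y + v, z] - padded[jx + u, jy + v, jz]
                                    d += g[u, v] * diff * diff
                            w = np.exp(-d / h2) * Atable[node_idx[x, y, z], node_idx[jx, jy, jz]]
                            num += w * data[jx, jy, jz]
                            den += w
                out[x, y, z] = num / den


def conn_nlm_oracle(pet: Volume3D, parc: ParcellationVolume | None,
                    H: HybridConnectivity | None, params: FilterParams) -> Volume3D:
    """Reference implementation of :func:`conn_nlm_filter` by literal loops.

    Same contract as the production filter; only accepts volumes of at most
    4096 voxels. With ``parc`` and ``H`` both None it is the plain-NLM oracle.
    """
    if pet.data.size > _ORACLE_MAX_VOXELS:
        raise ValueError(f"oracle accepts at most {_ORACLE_MAX_VOXELS} voxels")
    mask = _validate_inputs(pet, parc, H)
    node_idx, Atable = _label_table(parc, H, pet.shape)
    kernel = gaussian_patch_kernel(params.patch_size, params.a)
    padded = np.ascontiguousarray(_padded_inplane(pet.data, params.patch_size // 2))
    wr, sr = _window_radii(params)
    out = pet.data.copy()
    _oracle_loops(padded, pet.data, mask, node_idx, Atable,
                  kernel.weights, params.h2, wr, sr, out)
    return pet.with_data(out)
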