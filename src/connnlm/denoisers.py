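"""scikit-learn style denoiser estimators.

Each denoiser is a transformer over :class:`~connnlm.io.Volume3D`: construct
with hyper-parameters, ``fit`` with the volume plus whatever side data the
method needs (parcellation, connectome, a noise region, a track-density
image), then ``transform`` the volume. Parameters left as ``None`` are
estimated during ``fit`` from the noise-proportional rules

    h² = C · σ²(PET in the noise region),   λ = B · σ²(TDI)

and stored as fitted attributes (``h2_``, ``lam_``). The module-level
functions in :mod:`connnlm.filtering` are thin wrappers over these classes.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.restoration import denoise_tv_chambolle
from sklearn.base import BaseEstimator, TransformerMixin

from .connectivity import HybridConnectivity, estimate_lambda, normalize_sc
from .io import ConnectomeMatrix, FilterParams, ParcellationVolume, Volume3D

__all__ = ["ConnNLMDenoiser", "NLMDenoiser", "GaussianDenoiser", "TVDenoiser"]

_FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


def _check_volume(X) -> Volume3D:
    if isinstance(X, Volume3D):
        return X
    return Volume3D(data=np.asarray(X, dtype=np.float64))


class ConnNLMDenoiser(TransformerMixin, BaseEstimator):
    """Connectome-weighted non-local means denoiser.

    Parameters
    ----------
    h2 : float or None
        Smoothing strength h². ``None`` estimates C·σ² from ``noise_mask``.
    a : float
        Std (voxels) of the Gaussian kernel weighting the patch distance.
    patch_size : int
        Odd in-plane patch size M (patches are M×M, 2D axial).
    window : "whole_volume" or (N, S)
        3D search window; the default follows the whole-volume convention.
    lam : float or None
        Connectivity ratio λ. ``None`` estimates B·σ²(TDI) from ``tdi``.
    C, B : float
        Constants of the two noise-proportional estimation rules.

    Attributes
    ----------
    h2_, lam_ : float
        Resolved parameters after ``fit``.
    sc_norm_ : ConnectomeMatrix
        The [0,1]-normalized connectivity matrix.
    hybrid_ : HybridConnectivity
        The fitted local/distant weighting.
    params_ : FilterParams
        The validated parameter bundle used by ``transform``.
    """

    def __init__(self, h2: float | None = 0.25, a: float = 1.0, patch_size: int = 5,
                 window="whole_volume", lam: float | None = 1.0,
                 C: float = 8.0, B: float = 0.5e-5):
        self.h2 = h2
        self.a = a
        self.patch_size = patch_size
        self.window = window
        self.lam = lam
        self.C = C
        self.B = B

    def fit(self, X, y=None, *, parcellation: ParcellationVolume,
            connectome: ConnectomeMatrix, noise_mask: np.ndarray | None = None,
            tdi: Volume3D | None = None):
        from .filtering import estimate_h2

        X = _check_volume(X)
        if parcellation.shape != X.shape:
            raise ValueError("parcellation shape must match volume shape")
        self.sc_norm_ = connectome if connectome.normalized else normalize_sc(connectome)
        if self.h2 is not None:
            self.h2_ = float(self.h2)
        else:
            if noise_mask is None:
                raise ValueError("h2=None requires a noise_mask to estimate h2 = C·σ²")
            self.h2_ = estimate_h2(X, noise_mask, self.C)
        if self.h2_ <= 0:
            raise ValueError("estimated h2 is zero (constant noise region); supply h2 explicitly")
        if self.lam is not None:
            self.lam_ = float(self.lam)
        else:
            if tdi is None:
                raise ValueError("lam=None requires a TDI volume to estimate lam = B·σ²")
            self.lam_ = estimate_lambda(tdi, self.B)
        self.hybrid_ = HybridConnectivity(sc_norm=self.sc_norm_, lam=self.lam_)
        self.params_ = FilterParams(h2=self.h2_, a=self.a, patch_size=self.patch_size,
                                    window=self.window, lam=self.lam_)
        self.parcellation_ = parcellation
        return self

    def transform(self, X) -> Volume3D:
        from .filtering import _run_filter

        if not hasattr(self, "hybrid_"):
            raise RuntimeError("ConnNLMDenoiser is not fitted")
        X = _check_volume(X)
        return _run_filter(X, self.parcellation_, self.hybrid_, self.params_)


class NLMDenoiser(TransformerMixin, BaseEstimator):
    """Plain non-local means (hybrid connectivity A ≡ 1 everywhere)."""

    def __init__(self, h2: float | None = 0.25, a: float = 1.0, patch_size: int = 5,
                 window="whole_volume", C: float = 8.0):
        self.h2 = h2
        self.a = a
        self.patch_size = patch_size
        self.window = window
        self.C = C

    def fit(self, X, y=None, *, noise_mask: np.ndarray | None = None):
        from .filtering import estimate_h2

        X = _check_volume(X)
        if self.h2 is not None:
            self.h2_ = float(self.h2)
        else:
            if noise_mask is None:
                raise ValueError("h2=None requires a noise_mask to estimate h2 = C·σ²")
            self.h2_ = estimate_h2(X, noise_mask, self.C)
        if self.h2_ <= 0:
            raise ValueError("estimated h2 is zero (constant noise region); supply h2 explicitly")
        self.params_ = FilterParams(h2=self.h2_, a=self.a, patch_size=self.patch_size,
                                    window=self.window, lam=0.0)
        return self

    def transform(self, X) -> Volume3D:
        from .filtering import _run_filter

        if not hasattr(self, "params_"):
            raise RuntimeError("NLMDenoiser is not fitted")
        X = _check_volume(X)
        return _run_filter(X, None, None, self.params_)


class GaussianDenoiser(TransformerMixin, BaseEstimator):
    """Isotropic 3D Gaussian smoothing baseline, reflect boundary."""

    def __init__(self, fwhm: float = 4.0):
        self.fwhm = fwhm

    def fit(self, X, y=None):
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        self.sigma_ = float(self.fwhm) * _FWHM_TO_SIGMA
        return self

    def transform(self, X) -> Volume3D:
        if not hasattr(self, "sigma_"):
            raise RuntimeError("GaussianDenoiser is not fitted")
        X = _check_volume(X)
        out = ndimage.gaussian_filter(X.data, sigma=self.sigma_, mode="reflect")
        return X.with_data(out)


class TVDenoiser(TransformerMixin, BaseEstimator):
    """Total-variation (ROF-type, Chambolle) denoising baseline."""

    def __init__(self, weight: float = 0.1, n_iter: int = 200):
        self.weight = weight
        self.n_iter = n_iter

    def fit(self, X, y=None):
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        self.weight_ = float(self.weight)
        return self

    def transform(self, X) -> Volume3D:
        if not hasattr(self, "weight_"):
            raise RuntimeError("TVDenoiser is not fitted")
        X = _check_volume(X)
        out = denoise_tv_chambolle(X.data, weight=self.weight_, max_num_iter=self.n_iter)
        return X.with_data(out)
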