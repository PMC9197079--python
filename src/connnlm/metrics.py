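"""Quantitative evaluation of filtered images against ground truth.

Lesion metrics use medians because a lesion ROI can cover a bimodal intensity
distribution; the mean would bias the quantification. Noise is measured in
the normal grey-matter (GM) region with lesions excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import MetricsReport, Volume3D

__all__ = ["RegionMasks", "mse", "cnr", "crc", "average_variance", "evaluate"]


@dataclass
class RegionMasks:
    """Normal-GM background, named lesion ROIs, and their true contrasts CR."""

    gm: np.ndarray
    lesions: dict[str, np.ndarray] = field(default_factory=dict)
    true_contrast: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gm = np.asarray(self.gm, dtype=bool)
        if not self.gm.any():
            raise ValueError("GM mask is empty")
        for name, m in self.lesions.items():
            m = np.asarray(m, dtype=bool)
            if m.shape != self.gm.shape:
                raise ValueError(f"lesion mask {name!r} shape mismatch")
            if not m.any():
                raise ValueError(f"lesion mask {name!r} is empty")
            if (m & self.gm).any():
                raise ValueError(f"lesion mask {name!r} overlaps the normal-GM mask")
            self.lesions[name] = m


def mse(filtered: Volume3D, truth: Volume3D, mask: np.ndarray | None = None) -> float:
    """Mean squared error (1/N)·Σ (x_true − x)² over ``mask`` (default: all voxels).

    The conventional evaluation region is the brain mask: including
    background air would dilute the error with trivially-zero voxels.
    """
    if filtered.shape != truth.shape:
        raise ValueError("filtered and truth shapes differ")
    if mask is None:
        mask = np.ones(truth.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty MSE mask")
    diff = truth.data[mask] - filtered.data[mask]
    return float(np.mean(diff * diff))


def _masked(img: Volume3D, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    vals = img.data[mask]
    if vals.size == 0:
        raise ValueError("empty region mask")
    return vals


def cnr(img: Volume3D, lesion: np.ndarray, gm: np.ndarray,
        noise_stat: str = "sd") -> float:
    """Lesion contrast-to-noise ratio (M_L − M_GM) / σ_GM.

    M_L and M_GM are median intensities over the lesion and normal-GM masks.
    ``noise_stat`` selects the GM noise measure: ``"sd"`` (sample standard
    deviation, the conventional CNR denominator matching the symbol σ) or
    ``"var"`` (sample variance).
    """
    lesion_vals = _masked(img, lesion)
    gm_vals = _masked(img, gm)
    if gm_vals.size < 2:
        raise ValueError("need at least 2 GM voxels for a noise estimate")
    var = float(np.var(gm_vals, ddof=1))
    if var == 0:
        raise ValueError("zero GM spread: CNR undefined")
    if noise_stat == "sd":
        noise = float(np.sqrt(var))
    elif noise_stat == "var":
        noise = var
    else:
        raise ValueError(f"noise_stat must be 'sd' or 'var', got {noise_stat!r}")
    return float((np.median(lesion_vals) - np.median(gm_vals)) / noise)


def crc(img: Volume3D, lesion: np.ndarray, gm: np.ndarray, CR: float) -> float:
    """Lesion contrast recovery coefficient 100·(M_L/M_GM − 1)/(CR − 1), percent."""
    if CR == 1:
        raise ValueError("CRC undefined for true contrast CR = 1")
    m_l = float(np.median(_masked(img, lesion)))
    m_gm = float(np.median(_masked(img, gm)))
    if m_gm == 0:
        raise ValueError("zero GM median: CRC undefined")
    return float(100.0 * (m_l / m_gm - 1.0) / (CR - 1.0))


def average_variance(img: Volume3D, lesion: np.ndarray, gm: np.ndarray) -> float:
    """Mean of the GM and lesion sample variances, (σ²_GM + σ²_lesion)/2."""
    gm_vals = _masked(img, gm)
    lesion_vals = _masked(img, lesion)
    if gm_vals.size < 2 or lesion_vals.size < 2:
        raise ValueError("need at least 2 voxels in each region for a variance")
    return float((np.var(gm_vals, ddof=1) + np.var(lesion_vals, ddof=1)) / 2.0)


def evaluate(img: Volume3D, truth: Volume3D, masks: RegionMasks,
             mse_mask: np.ndarray | None = None,
             noise_stat: str = "sd") -> MetricsReport:
    """Full report: MSE vs truth plus per-lesion CNR / CRC and region variances."""
    if mse_mask is None:
        mse_mask = img.mask  # brain mask when present, else whole grid
    report = MetricsReport(
        mse=mse(img, truth, mse_mask),
        cnr={name: cnr(img, m, masks.gm, noise_stat=noise_stat)
             for name, m in masks.lesions.items()},
        crc_percent={name: crc(img, m, masks.gm, masks.true_contrast[name])
                     for name, m in masks.lesions.items()
                     if name in masks.true_contrast},
        variances={"gm": float(np.var(img.data[masks.gm], ddof=1)),
                   **{name: float(np.var(img.data[m], ddof=1))
                      for name, m in masks.lesions.items()}},
    )
    report.validate()
    return report
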