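"""Parameter sweeps and filter comparisons on phantom bundles.

These drive the two standard evaluation protocols: a (h², λ) grid scored by
per-lesion CNR (to pick filter parameters), and a cross-filter comparison
where each method is run over a parameter series spanning a comparable range
of residual noise variance, scored by whole-brain MSE and per-lesion CRC.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .connectivity import normalize_sc
from .denoisers import ConnNLMDenoiser, GaussianDenoiser, NLMDenoiser, TVDenoiser
from .io import (
    Volume3D,
    read_connectome,
    read_parcellation,
    read_region_masks,
    read_volume,
)
from .metrics import average_variance, cnr, crc, mse
from .phantom import PhantomBundle

__all__ = ["sweep", "compare_filters", "load_bundle"]


def _score(img: Volume3D, bundle: PhantomBundle, noise_stat: str = "sd") -> dict:
    masks = bundle.masks
    row = {
        "mse": mse(img, bundle.truth, bundle.truth.effective_mask()),
        "variance_gm": float(np.var(img.data[masks.gm], ddof=1)),
    }
    for name, lmask in masks.lesions.items():
        row[f"cnr_{name}"] = cnr(img, lmask, masks.gm, noise_stat=noise_stat)
        row[f"crc_{name}"] = crc(img, lmask, masks.gm, masks.true_contrast[name])
        row[f"avg_variance_{name}"] = average_variance(img, lmask, masks.gm)
    return row


def sweep(bundle: PhantomBundle, h2_grid: Sequence[float], lam_grid: Sequence[float],
          patch_size: int = 5, a: float = 1.0, window="whole_volume",
          noise_stat: str = "sd") -> pd.DataFrame:
    """CNR/MSE scores of the connectome filter over an (h², λ) grid."""
    sc_norm = bundle.sc if bundle.sc.normalized else normalize_sc(bundle.sc)
    rows = []
    for h2 in h2_grid:
        for lam in lam_grid:
            est = ConnNLMDenoiser(h2=h2, a=a, patch_size=patch_size,
                                  window=window, lam=lam)
            est.fit(bundle.noisy, parcellation=bundle.parc, connectome=sc_norm)
            filtered = est.transform(bundle.noisy)
            rows.append({"h2": h2, "lam": lam, **_score(filtered, bundle, noise_stat)})
    return pd.DataFrame(rows)


def compare_filters(bundle: PhantomBundle,
                    conn_series: Sequence[tuple[float, float]] = ((0.25, 0.0), (0.25, 0.01), (0.25, 1.0), (0.25, 10.0), (0.25, 100.0), (0.3, 1.0)),
                    nlm_series: Sequence[float] = (0.01, 0.02, 0.05, 0.1, 0.25, 0.4),
                    gf_series: Sequence[float] = (0.8, 1.2, 1.8, 2.5, 3.5, 5.0),
                    tv_series: Sequence[float] = (0.02, 0.05, 0.1, 0.15, 0.25, 0.4),
                    patch_size: int = 5, a: float = 1.0,
                    noise_stat: str = "sd") -> pd.DataFrame:
    """MSE / CRC / variance tables for CONN-NLM against baseline filters.

    Each filter is run over its own parameter series; series are meant to span
    a comparable range of residual GM noise variance so that MSE-vs-variance
    and CRC-vs-average-variance curves can be compared across methods. An
    unfiltered row is always included.
    """
    sc_norm = bundle.sc if bundle.sc.normalized else normalize_sc(bundle.sc)
    rows = [{"filter": "unfiltered", "param_name": "", "param_value": np.nan,
             **_score(bundle.noisy, bundle, noise_stat)}]
    for h2, lam in conn_series:
        est = ConnNLMDenoiser(h2=h2, a=a, patch_size=patch_size, lam=lam)
        est.fit(bundle.noisy, parcellation=bundle.parc, connectome=sc_norm)
        rows.append({"filter": "conn_nlm", "param_name": "h2,lam",
                     "param_value": float(lam), "h2": float(h2),
                     **_score(est.transform(bundle.noisy), bundle, noise_stat)})
    for h2 in nlm_series:
        est = NLMDenoiser(h2=h2, a=a, patch_size=patch_size).fit(bundle.noisy)
        rows.append({"filter": "nlm", "param_name": "h2", "param_value": float(h2),
                     **_score(est.transform(bundle.noisy), bundle, noise_stat)})
    for fwhm in gf_series:
        est = GaussianDenoiser(fwhm=fwhm).fit(bundle.noisy)
        rows.append({"filter": "gaussian", "param_name": "fwhm", "param_value": float(fwhm),
                     **_score(est.transform(bundle.noisy), bundle, noise_stat)})
    for weight in tv_series:
        est = TVDenoiser(weight=weight).fit(bundle.noisy)
        rows.append({"filter": "tv", "param_name": "weight", "param_value": float(weight),
                     **_score(est.transform(bundle.noisy), bundle, noise_stat)})
    return pd.DataFrame(rows)


def load_bundle(bundle_dir: str | Path) -> PhantomBundle:
    """Load a phantom bundle previously written by ``connnlm phantom``."""
    import yaml

    from .phantom import PhantomConfig

    d = Path(bundle_dir)
    truth = read_volume(d / "truth.nii.gz")
    noisy = read_volume(d / "noisy.nii.gz")
    parc = read_parcellation(d / "parc.nii.gz")
    sc = read_connectome(d / "sc.csv")
    masks = read_region_masks(d / "masks.yaml")
    cfg_path = d / "config.yaml"
    cfg = None
    if cfg_path.exists():
        raw = yaml.safe_load(cfg_path.read_text())
        raw["shape"] = tuple(raw["shape"])
        raw["lesion_specs"] = [tuple(s) for s in raw["lesion_specs"]]
        raw["connected_pairs"] = [tuple(p) for p in raw["connected_pairs"]]
        cfg = PhantomConfig(**raw)
    brain = truth.data > 0
    truth.mask = brain
    noisy.mask = brain
    return PhantomBundle(truth=truth, noisy=noisy, parc=parc, masks=masks,
                         sc=sc, config=cfg)
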