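"""Domain types and file I/O.

Volumes and parcellations travel as NIfTI-1, connectome matrices as CSV/TSV,
metric reports as JSON, region masks as NIfTI + a YAML manifest. All internal
computation is double precision; volumes are written as 32-bit float, the
common neuroimaging convention.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Volume3D",
    "ParcellationVolume",
    "ConnectomeMatrix",
    "FilterParams",
    "MetricsReport",
    "read_volume",
    "write_volume",
    "read_parcellation",
    "write_parcellation",
    "read_connectome",
    "write_connectome",
    "read_report",
    "write_report",
    "read_region_masks",
    "write_region_masks",
]


@dataclass
class Volume3D:
    """A 3D scalar intensity grid (PET, ground truth, TDI, ...).

    Parameters
    ----------
    data : ndarray
        3D array of finite real intensities, arbitrary activity units.
    spacing : tuple of float
        Per-axis voxel size in mm; metadata only, no operation depends on it.
    mask : ndarray of bool, optional
        Brain (or GM) mask; same shape as ``data`` when present.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        if not np.all(np.isfinite(self.data)):
            idx = np.unravel_index(
                int(np.argmin(np.isfinite(self.data))), self.data.shape
            )
            raise ValueError(
                f"non-finite voxel value at index {tuple(int(i) for i in idx)}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError(
                    f"mask shape {self.mask.shape} != data shape {self.data.shape}"
                )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def effective_mask(self) -> np.ndarray:
        """The mask, or an all-True array when no mask is set."""
        if self.mask is None:
            return np.ones(self.data.shape, dtype=bool)
        return self.mask

    def with_data(self, data: np.ndarray) -> "Volume3D":
        """A copy of this volume carrying new intensities."""
        return Volume3D(data=data, spacing=self.spacing, mask=self.mask)


@dataclass
class ParcellationVolume:
    """Integer node label per voxel; 0 means "not in any node"."""

    labels: np.ndarray
    node_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected 3D parcellation, got {self.labels.ndim}D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = self.labels.astype(np.int64)
            if not np.array_equal(as_int, self.labels):
                raise ValueError("parcellation labels must be integers")
            self.labels = as_int
        if self.labels.min() < 0:
            raise ValueError("parcellation labels must be non-negative")
        present = sorted(int(v) for v in np.unique(self.labels) if v > 0)
        if not self.node_ids:
            self.node_ids = present
        else:
            self.node_ids = sorted(int(v) for v in self.node_ids)
            missing = set(present) - set(self.node_ids)
            if missing:
                raise ValueError(f"labels {sorted(missing)} not in node_ids")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape


@dataclass
class ConnectomeMatrix:
    """Symmetric non-negative node-by-node structural connectivity matrix.

    ``normalized=False`` marks raw streamline-type weights; ``True`` marks the
    log-transformed min-max form with all entries in [0, 1].
    """

    values: np.ndarray
    node_ids: list[int] = field(default_factory=list)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"connectome must be square, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("connectome contains non-finite entries")
        if np.any(self.values < 0):
            raise ValueError("connectome contains negative entries")
        asym = np.abs(self.values - self.values.T).max() if self.values.size else 0.0
        if asym > 1e-12:
            raise ValueError(f"connectome asymmetric (max |A-A.T| = {asym:g})")
        if self.normalized and self.values.size and self.values.max() > 1 + 1e-12:
            raise ValueError("normalized connectome must have entries in [0, 1]")
        if not self.node_ids:
            self.node_ids = list(range(1, self.values.shape[0] + 1))
        else:
            self.node_ids = [int(v) for v in self.node_ids]
        if len(self.node_ids) != self.values.shape[0]:
            raise ValueError("node_ids length must match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def index_of(self, node_id: int) -> int:
        try:
            return self.node_ids.index(int(node_id))
        except ValueError:
            raise KeyError(f"unknown node id {node_id}") from None


@dataclass
class FilterParams:
    """Tunable filter parameters.

    h2 : smoothing strength h² (scale of the exponential similarity kernel).
    a : std of the Gaussian kernel weighting the patch distance, in voxels.
    patch_size : odd in-plane patch size M (patches are M×M, 2D axial).
    window : "whole_volume", or (N, S) for an N×N in-plane box over S slices.
    lam : connectivity ratio λ balancing distant vs local smoothing.
    """

    h2: float = 0.25
    a: float = 1.0
    patch_size: int = 5
    window: str | tuple[int, int] = "whole_volume"
    lam: float = 1.0

    def __post_init__(self) -> None:
        if self.h2 <= 0:
            raise ValueError("h2 must be strictly positive (h2=0 means no averaging scale)")
        if self.a <= 0:
            raise ValueError("patch kernel std a must be positive")
        if self.patch_size < 1 or self.patch_size % 2 == 0:
            raise ValueError(f"patch_size must be odd and >= 1, got {self.patch_size}")
        if self.window != "whole_volume":
            n, s = self.window
            if n < 1 or n % 2 == 0 or s < 1:
                raise ValueError(f"window box must be (odd N, S>=1), got {self.window}")
            self.window = (int(n), int(s))
        if self.lam < 0:
            raise ValueError("lam must be non-negative")


@dataclass
class MetricsReport:
    """Evaluation summary: MSE, per-lesion CNR and CRC (%), per-region variances."""

    mse: float
    cnr: dict[str, float] = field(default_factory=dict)
    crc_percent: dict[str, float] = field(default_factory=dict)
    variances: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        vals = [self.mse, *self.cnr.values(), *self.crc_percent.values(), *self.variances.values()]
        for v in vals:
            if not math.isfinite(v):
                raise ValueError(f"metrics report contains non-finite value {v!r}")


# ---------------------------------------------------------------------------
# NIfTI volumes


def read_volume(path: str | Path) -> Volume3D:
    """Read a 3D NIfTI volume; spacing is taken from the header zooms."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D in {path.name}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume3D(data=data, spacing=spacing)


def write_volume(vol: Volume3D, path: str | Path, dtype=np.float32) -> None:
    affine = np.diag([*vol.spacing, 1.0])
    img = nib.Nifti1Image(vol.data.astype(dtype), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_parcellation(path: str | Path) -> ParcellationVolume:
    vol = read_volume(path)
    labels = np.rint(vol.data).astype(np.int64)
    if np.abs(vol.data - labels).max() > 1e-6:
        raise ValueError(f"parcellation {Path(path).name} has non-integer labels")
    return ParcellationVolume(labels=labels)


def write_parcellation(parc: ParcellationVolume, path: str | Path,
                       spacing: Sequence[float] = (1.0, 1.0, 1.0)) -> None:
    affine = np.diag([*spacing, 1.0])
    nib.save(nib.Nifti1Image(parc.labels.astype(np.int32), affine), str(path))


# ---------------------------------------------------------------------------
# Connectome CSV/TSV


def read_connectome(path: str | Path, normalized: bool = False) -> ConnectomeMatrix:
    """Read a node-by-node connectivity matrix from CSV or TSV.

    A header row of node ids is detected automatically; without one, rows are
    assigned ids 1..n in order (AAL-style consecutive labelling). Asymmetries
    up to 1e-9 are symmetrized by averaging; anything larger is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        df = pd.read_csv(path, sep=sep, header=None, comment="#",
                         float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty connectome file {path.name}") from None
    node_ids: list[int] = []
    arr = df.to_numpy()
    if arr.size == 0:
        raise ValueError(f"empty connectome file {path.name}")
    if arr.shape[0] == arr.shape[1] + 1:
        # one extra row: the first row is a header of node ids
        try:
            node_ids = [int(float(v)) for v in arr[0]]
        except (TypeError, ValueError):
            raise ValueError(f"unparseable header row in {path.name}") from None
        arr = arr[1:]
    try:
        arr = arr.astype(np.float64)
    except (TypeError, ValueError):
        raise ValueError(f"non-numeric entries in connectome {path.name}") from None
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"connectome in {path.name} is not square: shape {arr.shape}")
    if np.any(np.isnan(arr)):
        raise ValueError(f"NaN entries in connectome {path.name}")
    if np.any(arr < 0):
        raise ValueError(f"negative entries in connectome {path.name}")
    asym = np.abs(arr - arr.T).max()
    if asym > 1e-9:
        raise ValueError(f"asymmetric connectome in {path.name} (max |A-A.T| = {asym:g})")
    arr = (arr + arr.T) / 2.0
    return ConnectomeMatrix(values=arr, node_ids=node_ids, normalized=normalized)


def write_connectome(sc: ConnectomeMatrix, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.DataFrame(sc.values)
    df.to_csv(path, sep=sep, header=[str(i) for i in sc.node_ids], index=False)


# ---------------------------------------------------------------------------
# Reports and mask manifests


def write_report(report: MetricsReport, path: str | Path) -> None:
    report.validate()
    payload = {
        "mse": report.mse,
        "cnr": report.cnr,
        "crc_percent": report.crc_percent,
        "variances": report.variances,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> MetricsReport:
    payload = json.loads(Path(path).read_text())
    return MetricsReport(
        mse=float(payload["mse"]),
        cnr={k: float(v) for k, v in payload.get("cnr", {}).items()},
        crc_percent={k: float(v) for k, v in payload.get("crc_percent", {}).items()},
        variances={k: float(v) for k, v in payload.get("variances", {}).items()},
    )


def write_region_masks(masks: "RegionMasks", out_dir: str | Path,
                       spacing: Sequence[float] = (1.0, 1.0, 1.0),
                       manifest_name: str = "masks.yaml") -> Path:
    """Write GM and lesion masks as NIfTI plus a YAML manifest.

    Returns the manifest path. The manifest records relative mask filenames
    and the true lesion-to-background contrast CR of each lesion.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*spacing, 1.0])

    def _save(mask: np.ndarray, name: str) -> str:
        fname = f"{name}_mask.nii.gz"
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(out_dir / fname))
        return fname

    manifest = {
        "gm": _save(masks.gm, "gm"),
        "lesions": {name: _save(m, name) for name, m in masks.lesions.items()},
        "true_contrast": {k: float(v) for k, v in masks.true_contrast.items()},
    }
    mpath = out_dir / manifest_name
    mpath.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return mpath


def read_region_masks(manifest_path: str | Path) -> "RegionMasks":
    from .metrics import RegionMasks

    manifest_path = Path(manifest_path)
    manifest = yaml.safe_load(manifest_path.read_text())
    base = manifest_path.parent

    def _load(fname: str) -> np.ndarray:
        return np.asarray(nib.load(str(base / fname)).dataobj) > 0

    return RegionMasks(
        gm=_load(manifest["gm"]),
        lesions={k: _load(v) for k, v in manifest["lesions"].items()},
        true_contrast={k: float(v) for k, v in manifest["true_contrast"].items()},
    )
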