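"""Reading and writing OCT volumes, masks and measurement tables.

Conventions
-----------
A volume is an ``(n_bscans, n_ascans, n_depth)`` array of 8-bit intensities:
axis 0 is the slow (B-scan) axis, axis 1 the fast (A-scan) axis, axis 2 depth.
Physical voxel spacing ``(dy, dx, dz)`` is given in micrometres per voxel and
must always be supplied by the caller or a sidecar file — 8-bit exports carry
no physical metadata of their own.

Supported on-disk layouts:

* a directory of equally shaped 8-bit grayscale images (PNG/TIFF/JPG), one per
  B-scan, in lexicographic filename order; each image is stored as
  ``(n_ascans, n_depth)``;
* a multi-page TIFF stack with one page per B-scan;
* a raw ``.img`` byte dump accompanied by a JSON or YAML sidecar declaring at
  least ``shape: [n_bscans, n_ascans, n_depth]``.

JPG input is accepted but logged with a warning: lossy compression perturbs
local thresholding statistics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}

#: canonical column order of the flat per-sector metrics table
METRICS_COLUMNS = [
    "eye_id",
    "sector",
    "mchvd_um",
    "ivd_um",
    "cht_um",
    "cvi",
    "n_vessels_measured",
    "flags",
]


@dataclass
class OCTVolume:
    """An 8-bit SS-OCT volume with physical spacing and provenance.

    Parameters
    ----------
    intensities
        ``(n_bscans, n_ascans, n_depth)`` array, values in 0–255.
    spacing
        Voxel pitch ``(dy, dx, dz)`` in µm/voxel, all strictly positive.
    laterality
        ``"OD"`` (right eye), ``"OS"`` (left eye) or ``"unknown"``.
    quality_score
        Optional device quality score on the 0–10 scale.
    meta
        Free-form provenance mapping.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    laterality: str = "unknown"
    quality_score: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 3 or min(arr.shape) < 1:
            raise ValidationError(f"volume must be 3D with all dims >= 1, got shape {arr.shape}")
        if arr.dtype != np.uint8:
            if arr.min() < 0 or arr.max() > 255:
                raise ValidationError("intensities must lie within 0-255")
            arr = arr.astype(np.uint8)
        self.intensities = arr
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValidationError(f"spacing must be three positive values, got {self.spacing}")
        self.spacing = sp
        if self.laterality not in ("OD", "OS", "unknown"):
            raise ValidationError(f"laterality must be OD, OS or unknown, got {self.laterality!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def enface_shape(self) -> tuple[int, int]:
        return self.intensities.shape[:2]


@dataclass
class DiscMask:
    """En-face binary optic-disc mask; true columns are excluded from analysis."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValidationError("disc mask must be a 2D en-face image")


def _load_sidecar(path: Path) -> dict:
    for suffix in (".json", ".yaml", ".yml"):
        cand = path.with_suffix(suffix)
        if cand.exists():
            with open(cand) as fh:
                if suffix == ".json":
                    return json.load(fh)
                return yaml.safe_load(fh)
    raise FormatError(f"raw IMG file {path} has no JSON/YAML sidecar declaring its shape")


def _read_slice(p: Path) -> np.ndarray:
    if p.suffix.lower() in (".jpg", ".jpeg"):
        logger.warning("reading lossy JPG slice %s; compression artifacts perturb thresholding", p.name)
    img = iio.imread(p)
    if img.ndim == 3:  # collapse RGB(A) that encodes grayscale
        img = img[..., 0]
    return np.asarray(img, dtype=np.uint8)


def read_volume(
    path: str | Path,
    spacing: tuple[float, float, float] | None = None,
    laterality: str | None = None,
    quality_score: float | None = None,
) -> OCTVolume:
    """Read an OCT volume from a slice directory, a TIFF stack or raw IMG + sidecar.

    ``spacing`` may be omitted only when a sidecar supplies it.
    """
    path = Path(path)
    meta: dict = {"source": str(path)}
    sidecar: dict = {}
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
        if not files:
            raise FormatError(f"no image slices found in {path}")
        slices = [_read_slice(p) for p in files]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise FormatError(f"inconsistent slice shapes in {path}: {sorted(shapes)}")
        arr = np.stack(slices, axis=0)
    elif path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        if arr.ndim != 3:
            raise FormatError(f"TIFF stack {path} is not a 3D volume (shape {arr.shape})")
        arr = np.asarray(arr, dtype=np.uint8)
    elif path.suffix.lower() == ".img":
        sidecar = _load_sidecar(path)
        if "shape" not in sidecar:
            raise FormatError(f"sidecar for {path} lacks a 'shape' entry")
        shape = tuple(int(v) for v in sidecar["shape"])
        raw = np.fromfile(path, dtype=np.uint8)
        if raw.size != int(np.prod(shape)):
            raise FormatError(
                f"raw IMG size {raw.size} does not match sidecar shape {shape}"
            )
        arr = raw.reshape(shape)
        meta["sidecar"] = sidecar
    else:
        raise FormatError(f"unsupported volume path {path}")

    if spacing is None:
        spacing = sidecar.get("spacing")
        if spacing is None:
            raise ValidationError(f"spacing must be supplied for {path} (argument or sidecar)")
    if laterality is None:
        laterality = sidecar.get("laterality", "unknown")
    if quality_score is None:
        quality_score = sidecar.get("quality_score")
    return OCTVolume(arr, tuple(spacing), laterality, quality_score, meta)


def write_volume(volume: OCTVolume, path: str | Path, fmt: str = "tiff") -> Path:
    """Write a volume as a multi-page TIFF (``fmt="tiff"``) or a PNG slice directory."""
    path = Path(path)
    if fmt == "tiff":
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, volume.intensities, photometric="minisblack")
    elif fmt == "png_dir":
        path.mkdir(parents=True, exist_ok=True)
        width = len(str(volume.shape[0] - 1))
        for i, bscan in enumerate(volume.intensities):
            iio.imwrite(path / f"bscan_{i:0{width}d}.png", bscan)
    else:
        raise ValidationError(f"unknown volume format {fmt!r}")
    return path


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a binary mask volume or image as an 8-bit TIFF (255 = true)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(mask, bool) * np.uint8(255), photometric="minisblack")
    return path


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path)) > 0


def check_quality(volume: OCTVolume, min_score: float = 6.0) -> bool:
    """Gate a scan on the device quality score (default floor 6 of 10).

    A volume with no recorded score passes with a logged warning rather than
    being rejected, so externally curated datasets remain usable.
    """
    if volume.quality_score is None:
        logger.warning("volume has no quality score; passing quality gate unverified")
        return True
    return volume.quality_score >= min_score


def write_metrics(table: pd.DataFrame, path: str | Path) -> Path:
    """Write the per-sector metrics table to CSV with full float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in METRICS_COLUMNS if c in table.columns] + [
        c for c in table.columns if c not in METRICS_COLUMNS
    ]
    table.loc[:, cols].to_csv(path, index=False)
    return path


def read_metrics(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=True)
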