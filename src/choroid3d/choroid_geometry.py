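"""Choroid slab geometry: boundary surfaces, smoothing, rasterization, thickness.

The choroid is represented by two en-face height maps in voxel units: the
inner surface ``z_i(y, x)`` at the RPE–choriocapillaris junction and the outer
surface ``z_o(y, x)`` at the chorioscleral junction.  The slab is the half-open
axial interval ``[z_i, z_o)``, so the per-column thickness in voxels is exactly
``z_o - z_i`` and the slab voxel count is the exact denominator of the
choroidal vascularity index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .errors import IntegrityError, ValidationError
from .volume_io import OCTVolume

logger = logging.getLogger(__name__)

SECTOR_NAMES = ("central", "nasal", "temporal", "superior", "inferior")


@dataclass
class ChoroidBoundaries:
    """Inner/outer choroid surfaces as voxel-unit height maps plus a validity map."""

    inner: np.ndarray
    outer: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.inner = np.asarray(self.inner, dtype=float)
        self.outer = np.asarray(self.outer, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.inner.shape == self.outer.shape == self.valid.shape):
            raise ValidationError("boundary maps must share one en-face shape")
        bad = self.valid & (self.inner > self.outer)
        if bad.any():
            cols = np.argwhere(bad)[:10].tolist()
            raise IntegrityError(
                f"inner surface lies below outer surface at {int(bad.sum())} columns, "
                f"e.g. {cols}"
            )

    @property
    def enface_shape(self) -> tuple[int, int]:
        return self.inner.shape

    def thickness_voxels(self) -> np.ndarray:
        """Per-column slab thickness ``z_o - z_i``; NaN on invalid columns."""
        t = self.outer - self.inner
        return np.where(self.valid, t, np.nan)


def boundaries_from_heightmaps(
    inner: str | Path | np.ndarray, outer: str | Path | np.ndarray
) -> ChoroidBoundaries:
    """Load boundaries from CSV (row = y, col = x) or 16-bit TIFF height maps.

    NaN entries mark columns without a defined boundary and become invalid.
    """

    def _load(src):
        if isinstance(src, (str, Path)):
            src = Path(src)
            if src.suffix.lower() in (".tif", ".tiff"):
                return np.asarray(tifffile.imread(src), dtype=float)
            return np.loadtxt(src, delimiter=",", dtype=float, ndmin=2)
        return np.asarray(src, dtype=float)

    zi, zo = _load(inner), _load(outer)
    valid = np.isfinite(zi) & np.isfinite(zo)
    return ChoroidBoundaries(np.nan_to_num(zi), np.nan_to_num(zo), valid)


def boundaries_from_mask(mask: np.ndarray) -> ChoroidBoundaries:
    """Extract surfaces from a binary slab volume as first/one-past-last true voxel.

    With the half-open slab convention this is the exact inverse of
    :func:`choroid_mask` for any contiguous-per-column mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValidationError("slab mask must be a 3D volume")
    any_true = mask.any(axis=2)
    zi = np.argmax(mask, axis=2).astype(float)
    nz = mask.shape[2]
    zo = (nz - np.argmax(mask[:, :, ::-1], axis=2)).astype(float)
    zi[~any_true] = 0.0
    zo[~any_true] = 0.0
    return ChoroidBoundaries(zi, zo, any_true)


def load_boundaries(
    inner: str | Path | np.ndarray | None = None,
    outer: str | Path | np.ndarray | None = None,
    mask: str | Path | np.ndarray | None = None,
) -> ChoroidBoundaries:
    """Load choroid boundaries from height maps or from a labeled slab mask."""
    if mask is not None:
        if isinstance(mask, (str, Path)):
            mask = tifffile.imread(mask) > 0
        return boundaries_from_mask(mask)
    if inner is None or outer is None:
        raise ValidationError("provide either inner+outer height maps or a slab mask")
    return boundaries_from_heightmaps(inner, outer)


def _truncated_median(surface: np.ndarray, valid: np.ndarray, window: int) -> np.ndarray:
    """Edge-truncated 2D moving median ignoring invalid columns."""
    half = window // 2
    padded = np.full(
        (surface.shape[0] + 2 * half, surface.shape[1] + 2 * half), np.nan, dtype=float
    )
    inner_view = padded[half:-half or None, half:-half or None]
    inner_view[...] = np.where(valid, surface, np.nan)
    stack = np.empty((window * window,) + surface.shape, dtype=float)
    idx = 0
    for dy in range(window):
        for dx in range(window):
            stack[idx] = padded[dy : dy + surface.shape[0], dx : dx + surface.shape[1]]
            idx += 1
    with np.errstate(all="ignore"):
        med = np.nanmedian(stack, axis=0)
    return np.where(valid, med, surface)


def smooth_boundaries(b: ChoroidBoundaries, window_voxels: int = 5) -> ChoroidBoundaries:
    """Volumetric boundary smoothing: per-surface 2D moving median.

    The median over a ``window × window`` en-face neighborhood (truncated at
    the field edge, invalid columns excluded) suppresses isolated segmentation
    spikes without displacing smooth anatomy.  ``window_voxels=1`` is the
    identity.  Because the median is a monotone operator applied with identical
    windows to both surfaces, an input satisfying ``z_i <= z_o`` cannot produce
    a crossing; the invariant is re-checked and clamped defensively anyway.
    """
    if window_voxels < 1 or window_voxels % 2 == 0:
        raise ValidationError(f"smoothing window must be an odd integer >= 1, got {window_voxels}")
    if window_voxels == 1:
        return ChoroidBoundaries(b.inner.copy(), b.outer.copy(), b.valid.copy())
    zi = _truncated_median(b.inner, b.valid, window_voxels)
    zo = _truncated_median(b.outer, b.valid, window_voxels)
    crossing = b.valid & (zi > zo)
    if crossing.any():
        logger.warning("clamped %d crossing columns after smoothing", int(crossing.sum()))
        zo = np.where(crossing, zi, zo)
    return ChoroidBoundaries(zi, zo, b.valid.copy())


def choroid_mask(b: ChoroidBoundaries, n_depth: int) -> np.ndarray:
    """Rasterize the half-open slab ``[z_i, z_o)`` into a boolean volume."""
    z = np.arange(n_depth)
    zi = np.round(b.inner).astype(int)[..., None]
    zo = np.round(b.outer).astype(int)[..., None]
    return b.valid[..., None] & (z >= zi) & (z < zo)


def segment_choroid_fallback(
    volume: OCTVolume,
    prior_thickness_um: float = 300.0,
    rpe_search_sigma: float = 2.0,
    min_band_intensity: float = 50.0,
) -> ChoroidBoundaries:
    """Classical intensity-based choroid segmentation.

    A stand-in boundary finder so the pipeline runs end-to-end without an
    external segmentation model.  Per A-scan column: the brightest axial band
    is taken as the RPE complex; the inner boundary is the strongest negative
    axial gradient just below that band; the outer boundary is the strongest
    negative gradient within a window around ``inner + prior_thickness_um``.
    Columns with no detectable bright band are marked invalid, never filled.
    """
    vol = volume.intensities.astype(float)
    dz = volume.spacing[2]
    nz = vol.shape[2]
    smoothed = ndimage.gaussian_filter1d(vol, rpe_search_sigma, axis=2)
    peak = np.argmax(smoothed, axis=2)
    peak_val = np.max(smoothed, axis=2)
    valid = peak_val >= min_band_intensity

    grad = np.diff(smoothed, axis=2)  # grad[..., z] = I[z+1] - I[z]
    zidx = np.arange(nz - 1)

    # inner boundary: strongest drop within a short window below the RPE peak
    inner_lo = peak[..., None]
    inner_hi = peak[..., None] + max(3, int(round(30.0 / dz)))
    in_win = (zidx >= inner_lo) & (zidx < inner_hi)
    g_inner = np.where(in_win, grad, np.inf)
    inner = np.argmin(g_inner, axis=2) + 1

    # outer boundary: strongest drop around the prior-thickness depth
    prior_vox = prior_thickness_um / dz
    out_lo = inner[..., None] + max(1, int(round(0.5 * prior_vox)))
    out_hi = inner[..., None] + int(round(1.6 * prior_vox))
    out_win = (zidx >= out_lo) & (zidx < np.minimum(out_hi, nz - 1))
    g_outer = np.where(out_win, grad, np.inf)
    has_out = np.isfinite(g_outer).any(axis=2)
    outer = np.argmin(np.where(np.isfinite(g_outer), g_outer, np.inf), axis=2) + 1
    valid &= has_out

    inner = inner.astype(float)
    outer = np.maximum(outer, inner).astype(float)
    n_invalid = int((~valid).sum())
    if n_invalid:
        logger.info("fallback segmentation: %d columns without detectable band", n_invalid)
    inner[~valid] = 0.0
    outer[~valid] = 0.0
    return ChoroidBoundaries(inner, outer, valid)


def compute_cht(
    b: ChoroidBoundaries,
    dz: float,
    sector_labels: np.ndarray | None = None,
    sector_codes: dict[str, int] | None = None,
) -> pd.Series:
    """Per-sector and whole-field mean choroidal thickness in µm.

    ``ChT(y, x) = (z_o - z_i) · dz``; each sector value averages the valid,
    non-excluded columns of that sector; the ``average`` entry averages all
    analyzed columns of the field (not the mean of sector means).  Sectors with
    no valid column yield NaN, never zero.
    """
    if dz <= 0:
        raise ValidationError("dz must be positive")
    tvox = b.thickness_voxels()
    cht = tvox * dz
    out: dict[str, float] = {}
    if sector_labels is None:
        out["average"] = float(np.nanmean(cht)) if b.valid.any() else np.nan
        return pd.Series(out, name="cht_um")
    from .sectors import SECTOR_CODES  # local import to avoid a cycle

    codes = sector_codes or SECTOR_CODES
    analyzed = b.valid & (sector_labels != codes["excluded"])
    for name in SECTOR_NAMES:
        sel = analyzed & (sector_labels == codes[name])
        out[name] = float(cht[sel].mean()) if sel.any() else np.nan
    out["average"] = float(cht[analyzed].mean()) if analyzed.any() else np.nan
    return pd.Series(out, name="cht_um")
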