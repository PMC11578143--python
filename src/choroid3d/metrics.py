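"""Sector metrics assembly (CVI, ChT, MChVD, IVD) and reliability statistics.

CVI is the ratio of luminal (vessel) volume to total choroidal volume,
computed per sector as an exact voxel-count ratio; the whole-field value is
the ratio over all analyzed columns, i.e. the voxel-count-weighted mean of the
sector values, not their unweighted mean.

Inter-grader reliability uses the single-measurement, absolute-agreement,
two-way random-effects intraclass correlation coefficient with the standard
mean-squares decomposition and an F-based 95% confidence interval, banded at
0.5 / 0.75 / 0.9 (poor / moderate / good / excellent).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .choroid_geometry import SECTOR_NAMES
from .errors import IntegrityError, ValidationError
from .metrology import VesselMeasurementSet
from .sectors import SECTOR_CODES, SectorGrid
from .volume_io import METRICS_COLUMNS

logger = logging.getLogger(__name__)


def compute_cvi(
    luminal: np.ndarray, choroid: np.ndarray, grid: SectorGrid | None = None
) -> pd.Series:
    """Per-sector and whole-field choroidal vascularity index.

    ``CVI(sector) = luminal voxels / choroid voxels`` over the non-excluded
    columns of that sector.  Sectors with no choroid voxels yield NaN (flagged
    by the caller), never zero.
    """
    luminal = np.asarray(luminal, dtype=bool)
    choroid = np.asarray(choroid, dtype=bool)
    if luminal.shape != choroid.shape:
        raise ValidationError("luminal and choroid masks must share a shape")
    if (luminal & ~choroid).any():
        raise ValidationError("luminal mask must be a subset of the choroid mask")
    col_lum = luminal.sum(axis=2).astype(np.int64)
    col_cho = choroid.sum(axis=2).astype(np.int64)
    out: dict[str, float] = {}
    if grid is None:
        total = int(col_cho.sum())
        out["average"] = float(col_lum.sum() / total) if total else np.nan
        return pd.Series(out, name="cvi")
    analyzed = grid.labels != SECTOR_CODES["excluded"]
    for name in SECTOR_NAMES:
        sel = analyzed & (grid.labels == SECTOR_CODES[name])
        denom = int(col_cho[sel].sum())
        out[name] = float(col_lum[sel].sum() / denom) if denom else np.nan
    denom = int(col_cho[analyzed].sum())
    out["average"] = float(col_lum[analyzed].sum() / denom) if denom else np.nan
    return pd.Series(out, name="cvi")


def assemble_table(
    cht: pd.Series,
    cvi: pd.Series,
    measurements: dict[str, VesselMeasurementSet],
    eye_id: str = "eye",
) -> pd.DataFrame:
    """One analysis-ready row per sector plus an ``average`` row.

    The average MChVD/IVD pools all recorded measurement sites across sectors
    (missing sites are excluded from means, never imputed as zero); average
    ChT and CVI are the whole-field values carried in by their inputs.
    """
    sectors = set(SECTOR_NAMES)
    for name, series in (("cht", cht), ("cvi", cvi)):
        missing = sectors - set(series.index)
        if missing:
            raise IntegrityError(f"{name} input lacks sectors {sorted(missing)}")
    if set(measurements) != sectors:
        raise IntegrityError(
            f"measurements cover {sorted(measurements)}, expected {sorted(sectors)}"
        )
    rows = []
    all_diam: list[float] = []
    all_ivd: list[float] = []
    for name in SECTOR_NAMES:
        m = measurements[name]
        all_diam.extend(m.diameters_um)
        all_ivd.extend(m.ivds_um)
        rows.append(
            {
                "eye_id": eye_id,
                "sector": name,
                "mchvd_um": m.mchvd_um,
                "ivd_um": m.ivd_um,
                "cht_um": float(cht[name]),
                "cvi": float(cvi[name]),
                "n_vessels_measured": m.n_vessels,
                "flags": ";".join(m.flags),
            }
        )
    rows.append(
        {
            "eye_id": eye_id,
            "sector": "average",
            "mchvd_um": float(np.mean(all_diam)) if all_diam else np.nan,
            "ivd_um": float(np.mean(all_ivd)) if all_ivd else np.nan,
            "cht_um": float(cht["average"]),
            "cvi": float(cvi["average"]),
            "n_vessels_measured": int(sum(m.n_vessels for m in measurements.values())),
            "flags": "",
        }
    )
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)


# ---------------------------------------------------------------------------
# reliability


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    band: str
    n_subjects: int
    n_raters: int


def icc_band(value: float) -> str:
    """Reliability band: [0, 0.5) poor, [0.5, 0.75) moderate, [0.75, 0.9) good, >= 0.9 excellent."""
    if not np.isfinite(value):
        return "undefined"
    if value < 0.5:
        return "poor"
    if value < 0.75:
        return "moderate"
    if value < 0.9:
        return "good"
    return "excellent"


def icc_absolute_agreement(matrix: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(A,1): two-way random effects, single measurement, absolute agreement.

    ``matrix`` is subjects × raters with no missing cells (rows containing
    NaN are dropped with a log message).  The estimate uses the mean-squares
    decomposition

        ICC = (MSR - MSE) / (MSR + (k-1)·MSE + k·(MSC - MSE)/n)

    with MSR/MSC/MSE the between-subject, between-rater and residual mean
    squares, and the McGraw–Wong F-based interval for the CI.  Zero total
    variance leaves the ICC undefined (NaN, band "undefined").
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValidationError("ratings must be a 2D subjects x raters matrix")
    keep = ~np.isnan(m).any(axis=1)
    if (~keep).any():
        logger.info("dropping %d subjects with missing ratings", int((~keep).sum()))
        m = m[keep]
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValidationError(f"need >= 2 subjects and >= 2 raters, got {n} x {k}")

    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((m - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    total_var = msr + msc + mse
    if total_var <= 0 or np.sum((m - grand) ** 2) == 0:
        logger.warning("zero total variance: ICC undefined")
        return ICCResult(np.nan, np.nan, np.nan, "undefined", n, k)

    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # McGraw & Wong F-based 95% CI for ICC(A,1)
    if np.isclose(icc, 1.0):
        lo = hi = 1.0
    else:
        a = (k * icc) / (n * (1.0 - icc))
        b = 1.0 + (k * icc * (n - 1.0)) / (n * (1.0 - icc))
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        denom_lo = f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        lo = n * (msr - f_l * mse) / denom_lo if denom_lo > 0 else np.nan
        denom_hi = k * msc + (k * n - k - n) * mse + n * f_u * msr
        hi = n * (f_u * msr - mse) / denom_hi if denom_hi > 0 else np.nan

    return ICCResult(float(icc), float(lo), float(hi), icc_band(float(icc)), n, k)


def icc_from_table(df: pd.DataFrame) -> ICCResult:
    """ICC from a long or wide ratings table.

    Wide: one column per rater.  Long: columns ``subject``, ``rater``,
    ``rating`` are pivoted first.
    """
    if {"subject", "rater", "rating"} <= set(df.columns):
        wide = df.pivot(index="subject", columns="rater", values="rating")
        return icc_absolute_agreement(wide.to_numpy())
    return icc_absolute_agreement(df.to_numpy())
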