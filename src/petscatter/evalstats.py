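"""Method-comparison machinery: masks, profiles, ROI stats, ICC, GMR.

These are the tools used to compare two scatter-correction routes on the
same data: slice-wise percent-difference profiles over tissue masks,
bilateral ROI means with left-to-right ratios, the intraclass correlation
coefficient ICC(2,1) (two-way random effects, single measurement,
absolute agreement), geometric mean (reduced major axis) regression, and
a patient-averaged absolute-difference table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RoiSpec",
    "tissue_masks",
    "slice_diff_profile",
    "roi_stats",
    "icc_2_1",
    "gmr_fit",
    "abs_diff_table",
]


def tissue_masks(
    gm_probability: np.ndarray,
    wm_probability: np.ndarray,
    threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean GM and WM masks by strict thresholding of probability maps.

    A voxel at exactly the threshold is excluded.  Overlapping masks (both
    probabilities above threshold somewhere) trigger a warning, since that
    can happen with synthetic maps.
    """
    gm_p = np.asarray(gm_probability, dtype=float)
    wm_p = np.asarray(wm_probability, dtype=float)
    for p in (gm_p, wm_p):
        if p.min() < 0 or p.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
    gm = gm_p > threshold
    wm = wm_p > threshold
    if np.any(gm & wm):
        import warnings

        warnings.warn("GM and WM masks overlap after thresholding", stacklevel=2)
    return gm, wm


def slice_diff_profile(
    img_a: np.ndarray, img_b: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """Per-slice percent difference 100*(mean_a - mean_b)/mean_b over a mask.

    Slices with an empty mask, or a zero reference mean, yield NaN (the
    undefined marker), never an exception.  Slice axis is the last axis.
    """
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if not (a.shape == b.shape == m.shape):
        raise ValueError("images and mask must share one grid")
    n_slices = a.shape[-1]
    out = np.full(n_slices, np.nan)
    for z in range(n_slices):
        mz = m[..., z]
        if not mz.any():
            continue
        mb = b[..., z][mz].mean()
        if mb == 0:
            continue
        out[z] = 100.0 * (a[..., z][mz].mean() - mb) / mb
    return out


@dataclass(frozen=True)
class RoiSpec:
    """One region of interest on the shared grid.

    ``shape`` is ``ellipse`` (16 x 32 mm default axes) or ``circle``
    (16 mm diameter); the ROI covers ``n_slices_averaged`` adjacent
    slices starting at ``slice_index`` and per-slice means are averaged.
    Bilateral ROIs are mirrored across the mid-sagittal plane x = nx/2.
    """

    name: str
    center_xy_vox: tuple[float, float]
    slice_index: int
    shape: str = "ellipse"
    axes_mm: tuple[float, float] = (16.0, 32.0)
    bilateral: bool = True
    n_slices_averaged: int = 3

    def __post_init__(self) -> None:
        if self.shape not in ("ellipse", "circle"):
            raise ValueError("shape must be 'ellipse' or 'circle'")
        if self.n_slices_averaged < 1:
            raise ValueError("need at least one slice")

    def _mask2d(self, nx: int, ny: int, voxel_xy_mm: tuple[float, float], mirror: bool):
        cx, cy = self.center_xy_vox
        if mirror:
            cx = (nx - 1) - cx
        if self.shape == "circle":
            ax = ay = self.axes_mm[0] / 2.0
        else:
            ax, ay = self.axes_mm[0] / 2.0, self.axes_mm[1] / 2.0
        x = (np.arange(nx)[:, None] - cx) * voxel_xy_mm[0]
        y = (np.arange(ny)[None, :] - cy) * voxel_xy_mm[1]
        return (x / ax) ** 2 + (y / ay) ** 2 <= 1.0

    def means(
        self, volume: np.ndarray, voxel_size_mm: tuple[float, float, float]
    ) -> dict[str, float]:
        """Per-side ROI means averaged over the adjacent slices."""
        nx, ny, nz = volume.shape
        z0, z1 = self.slice_index, self.slice_index + self.n_slices_averaged
        if z0 < 0 or z1 > nz:
            raise ValueError(f"ROI {self.name!r} slices outside the image")
        sides = {"right": False, "left": True} if self.bilateral else {"mid": False}
        out = {}
        for side, mirror in sides.items():
            m = self._mask2d(nx, ny, voxel_size_mm[:2], mirror)
            if not m.any():
                raise ValueError(f"ROI {self.name!r} covers no voxels")
            out[side] = float(np.mean([volume[:, :, z][m].mean() for z in range(z0, z1)]))
        return out


def roi_stats(
    volume: np.ndarray,
    rois: list[RoiSpec],
    voxel_size_mm: tuple[float, float, float],
) -> pd.DataFrame:
    """Per-ROI means, bilateral averages, and left-to-right ratios.

    Unilateral ROIs (midline structures) get no left/right entries and no
    ratio, mirroring how pons and midbrain are treated.
    """
    rows = []
    for roi in rois:
        m = roi.means(np.asarray(volume, dtype=float), voxel_size_mm)
        if roi.bilateral:
            rows.append(
                {
                    "roi": roi.name,
                    "left": m["left"],
                    "right": m["right"],
                    "mean": 0.5 * (m["left"] + m["right"]),
                    "lr_ratio": m["left"] / m["right"] if m["right"] != 0 else np.nan,
                }
            )
        else:
            rows.append(
                {"roi": roi.name, "left": np.nan, "right": np.nan, "mean": m["mid"], "lr_ratio": np.nan}
            )
    return pd.DataFrame(rows).set_index("roi")


def icc_2_1(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, single rater, absolute agreement.

    ``ratings`` is an (n subjects x k methods) matrix with no missing
    cells.  From the two-way ANOVA mean squares (BMS rows, JMS columns,
    EMS residual):

        ICC = (BMS - EMS) / (BMS + (k-1) EMS + k (JMS - EMS) / n)

    Returns NaN when the total variance is zero and the ratings are all
    identical columns of a constant (agreement undefined); identical
    non-constant columns give 1.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("ratings must be (n >= 2) x (k >= 2)")
    if not np.all(np.isfinite(m)):
        raise ValueError("ratings must have no missing cells")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    bms = ss_rows / (n - 1)
    jms = ss_cols / (k - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    denom = bms + (k - 1) * ems + k * (jms - ems) / n
    if denom == 0:
        return float("nan")
    return float((bms - ems) / denom)


def gmr_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Geometric mean (reduced major axis) regression.

    slope = sign(corr(x, y)) * sd(y)/sd(x); intercept through the means.
    Symmetric in the sense slope_xy * slope_yx = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need at least two matched points")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0:
        raise ValueError("x has zero variance")
    r = np.corrcoef(x, y)[0, 1] if sy > 0 else 0.0
    sign = 1.0 if r >= 0 else -1.0
    slope = sign * sy / sx
    return float(slope), float(y.mean() - slope * x.mean())


def abs_diff_table(
    values_a: pd.DataFrame, values_b: pd.DataFrame
) -> pd.DataFrame:
    """Patient-averaged absolute percent differences per ROI.

    Inputs are (subject x ROI) tables of matched values from two methods;
    each cell of the report is mean over subjects of 100*|a - b|/b for
    that ROI, plus a 'Total' row averaging over ROIs (unweighted).  Cells
    where the reference is 0 are NaN.
    """
    if not values_a.columns.equals(values_b.columns) or not values_a.index.equals(
        values_b.index
    ):
        raise ValueError("subject/ROI layout of the two tables must match")
    a = values_a.to_numpy(dtype=float)
    b = values_b.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(b != 0, 100.0 * np.abs(a - b) / np.abs(b), np.nan)
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        per_roi = np.nanmean(pct, axis=0)
        total = np.nanmean(per_roi)
    out = pd.DataFrame({"abs_diff_pct": per_roi}, index=values_a.columns)
    out.loc["Total"] = total
    return out
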