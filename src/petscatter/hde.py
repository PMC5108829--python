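"""Hybrid dual-energy-window (HDE) scatter correction — the reference.

The upper energy window (UEW) sees relatively little scatter, so its own
scatter can be removed with the deconvolution kernel; the remaining UEW
trues, scaled by the windows' true-efficiency ratio R, predict the SEW
trues, and the SEW scatter estimate is the difference

    scatter_SEW = SEW - R * (UEW - DEC_scatter(UEW)).

Because the estimate inherits UEW counting noise, it is optionally
smoothed with a total-preserving Gaussian before subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .containers import Sinogram
from .deccor import dec_estimate_scatter
from .kernel import KernelParams

__all__ = [
    "WindowRatio",
    "estimate_window_ratio",
    "hde_estimate_scatter",
    "hde_correct",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class WindowRatio:
    """Global scalar mapping UEW trues to SEW trues (>= 1 for nested windows)."""

    R: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.R) and self.R > 0):
            raise ValueError("window ratio must be finite and positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"R": self.R}))

    @classmethod
    def from_json(cls, path: str | Path) -> "WindowRatio":
        return cls(float(json.loads(Path(path).read_text())["R"]))


def estimate_window_ratio(
    sew_trues_cal: Sinogram, uew_trues_cal: Sinogram
) -> WindowRatio:
    """R = total SEW trues / total UEW trues from a scatter-free
    (or scatter-corrected) calibration acquisition."""
    uew_total = uew_trues_cal.counts.sum()
    if uew_total <= 0:
        raise ValueError("UEW calibration total must be positive")
    return WindowRatio(float(sew_trues_cal.counts.sum() / uew_total))


def _smooth_planes(counts: np.ndarray, sino: Sinogram, fwhm_cm: float) -> np.ndarray:
    """Total-preserving radial x axial Gaussian smoothing per view."""
    if fwhm_cm == 0:
        return counts
    geom = sino.geometry
    sig_r = fwhm_cm * _FWHM_TO_SIGMA / geom.radial_bin_cm
    sig_z = fwhm_cm * _FWHM_TO_SIGMA / geom.slice_thickness_cm
    return gaussian_filter(counts, sigma=(0.0, sig_r, sig_z), mode="reflect")


def hde_estimate_scatter(
    sew: Sinogram,
    uew: Sinogram,
    uew_params: KernelParams,
    ratio: WindowRatio,
    smooth_fwhm_cm: float = 2.0,
    mode: str = "zeropad",
) -> Sinogram:
    """SEW scatter estimate by the hybrid dual-energy-window combination."""
    if sew.counts.shape != uew.counts.shape:
        raise ValueError("SEW and UEW sinogram shapes differ")
    uew_scatter = dec_estimate_scatter(uew, uew_params, mode=mode)
    uew_trues = uew.counts - uew_scatter.counts
    raw = sew.counts - ratio.R * uew_trues
    est = _smooth_planes(raw, sew, smooth_fwhm_cm)
    est = np.clip(est, 0.0, None)
    return sew.with_counts(est, label="SCATTER", corrected=False)


def hde_correct(
    sew: Sinogram,
    uew: Sinogram,
    uew_params: KernelParams,
    ratio: WindowRatio,
    smooth_fwhm_cm: float = 2.0,
    mode: str = "zeropad",
    clamp: bool = True,
) -> tuple[Sinogram, Sinogram]:
    """Subtract the HDE scatter estimate from the SEW sinogram.

    Returns (corrected, scatter estimate); conservation
    ``sum(corrected) = sum(sew) - sum(scatter)`` holds pre-clamp.
    """
    scatter = hde_estimate_scatter(
        sew, uew, uew_params, ratio, smooth_fwhm_cm=smooth_fwhm_cm, mode=mode
    )
    corrected = sew.counts - scatter.counts
    if clamp:
        corrected = np.clip(corrected, 0.0, None)
    return (
        sew.with_counts(corrected, label="CORRECTED", corrected=True),
        scatter,
    )
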