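"""Deconvolution (convolution-subtraction) scatter correction.

The scatter estimate is obtained by convolving each view's radial x axial
plane of the measured standard-window sinogram with the empirical scatter
kernel, then subtracting it.  The kernel parameters depend on object
size: a calibration table maps the attenuating object's volume (from the
segmented transmission image) to (alpha, beta) by linear interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MuMap, Sinogram
from .kernel import KernelParams, scatter_convolve

__all__ = [
    "CalibrationTable",
    "object_volume",
    "params_for_volume",
    "dec_estimate_scatter",
    "dec_correct",
]

#: segmentation threshold on the transmission image, 1/cm
MU_SEGMENT_THRESHOLD = 0.06


@dataclass(frozen=True)
class CalibrationTable:
    """Rows of (object volume in cm^3 -> kernel parameters), ascending."""

    volumes_cm3: tuple[float, ...]
    params: tuple[KernelParams, ...]

    def __post_init__(self) -> None:
        if len(self.volumes_cm3) == 0:
            raise ValueError("calibration table needs at least one row")
        if len(self.volumes_cm3) != len(self.params):
            raise ValueError("volumes and params rows differ in length")
        v = np.asarray(self.volumes_cm3)
        if len(v) > 1 and not np.all(np.diff(v) > 0):
            raise ValueError("volumes must be strictly increasing")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "volume_cm3": self.volumes_cm3,
                "alpha": [p.alpha for p in self.params],
                "beta_cm2": [p.beta_cm2 for p in self.params],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CalibrationTable":
        df = pd.read_csv(path).sort_values("volume_cm3")
        return cls(
            tuple(float(v) for v in df["volume_cm3"]),
            tuple(
                KernelParams(float(a), float(b))
                for a, b in zip(df["alpha"], df["beta_cm2"])
            ),
        )


def object_volume(
    mu: MuMap, threshold_per_cm: float = MU_SEGMENT_THRESHOLD
) -> float:
    """Attenuating object volume (cm^3) by strict mu thresholding.

    Counts voxels with mu strictly above the threshold and multiplies by
    the voxel volume.  An empty segmentation returns 0 with a warning.
    """
    n = int(np.count_nonzero(mu.values > threshold_per_cm))
    if n == 0:
        warnings.warn("mu segmentation is empty; object volume is 0", stacklevel=2)
    return n * mu.voxel_volume_ml


def params_for_volume(table: CalibrationTable, volume_cm3: float) -> KernelParams:
    """Linearly interpolate alpha and beta at the given object volume.

    Outside the tabulated range the nearest end row is used (np.interp's
    clamping behaviour).
    """
    v = np.asarray(table.volumes_cm3)
    alpha = float(np.interp(volume_cm3, v, [p.alpha for p in table.params]))
    beta = float(np.interp(volume_cm3, v, [p.beta_cm2 for p in table.params]))
    return KernelParams(alpha, beta)


def dec_estimate_scatter(
    sino: Sinogram, params: KernelParams, mode: str = "zeropad"
) -> Sinogram:
    """Scatter estimate: per-view kernel convolution of the measured sinogram."""
    if sino.counts.min() < -1e-2 * max(float(sino.counts.max()), 1.0):
        raise ValueError("input sinogram must be nonnegative")
    geom = sino.geometry
    spacing = (geom.radial_bin_cm, geom.slice_thickness_cm)
    est = np.empty_like(sino.counts)
    for v in range(geom.n_views):
        est[v] = scatter_convolve(sino.counts[v], params, spacing, mode=mode)
    return sino.with_counts(est, label="SCATTER", corrected=False)


def dec_correct(
    sino: Sinogram,
    table_or_params: CalibrationTable | KernelParams,
    mu: MuMap | None = None,
    mode: str = "zeropad",
    clamp: bool = True,
    iterations: int = 1,
) -> tuple[Sinogram, Sinogram]:
    """Convolution-subtraction correction of a standard-window sinogram.

    With a calibration table, the kernel is looked up at the object volume
    segmented from ``mu``.  Returns (corrected, scatter estimate); the
    scatter estimate is always pre-clamp, so
    ``sum(sino) - sum(scatter) == sum(corrected)`` holds when ``clamp`` is
    off.  ``iterations`` > 1 refines the estimate as
    s_i = k (*) (p - s_{i-1}), approximating scatter convolved from trues
    rather than from prompts; the default is the single-pass scheme.
    """
    if isinstance(table_or_params, CalibrationTable):
        if mu is None:
            raise ValueError("a mu map is required to index the calibration table")
        params = params_for_volume(table_or_params, object_volume(mu))
    elif isinstance(table_or_params, KernelParams):
        params = table_or_params
    else:
        raise TypeError("expected a CalibrationTable or KernelParams")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")

    scatter = dec_estimate_scatter(sino, params, mode=mode)
    for _ in range(iterations - 1):
        refined = sino.with_counts(
            np.clip(sino.counts - scatter.counts, 0.0, None), corrected=True
        )
        scatter = dec_estimate_scatter(refined, params, mode=mode)
    corrected = sino.counts - scatter.counts
    if clamp:
        corrected = np.clip(corrected, 0.0, None)
    return (
        sino.with_counts(corrected, label="CORRECTED", corrected=True),
        scatter,
    )
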