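"""Core data containers: sinograms and voxel volumes, with file I/O.

Sinograms live in HDF5 (counts dataset + geometry attributes); volumes go
to NIfTI-1 with voxel sizes in mm in the header.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .geometry import ScannerGeometry

__all__ = [
    "WINDOW_LABELS",
    "Sinogram",
    "ActivityVolume",
    "MuMap",
    "read_sinogram",
    "write_sinogram",
    "read_volume",
    "write_volume",
]

WINDOW_LABELS = ("SEW", "UEW", "TRUES", "SCATTER", "CORRECTED", "ACF")

_GEOM_FIELDS = (
    "n_views",
    "n_radial",
    "radial_bin_cm",
    "n_slices",
    "slice_thickness_cm",
    "fov_radius_cm",
)


@dataclass
class Sinogram:
    """Projection counts indexed (view, radial, slice).

    ``counts`` must be finite everywhere and nonnegative unless
    ``corrected_flag`` is set (scatter subtraction may leave negatives
    before clamping).
    """

    counts: np.ndarray
    geometry: ScannerGeometry
    window_label: str = "TRUES"
    corrected_flag: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != self.geometry.shape:
            raise ValueError(
                f"counts shape {self.counts.shape} != geometry shape {self.geometry.shape}"
            )
        if self.window_label not in WINDOW_LABELS:
            raise ValueError(f"unknown window label {self.window_label!r}")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("sinogram counts must be finite")
        # measured windows are count data; derived planes (corrected,
        # scatter estimates) may carry small negatives before clamping.
        # Synthetic fixed-point data ring sub-promille negative at support
        # edges, so the check uses a relative floor rather than exact 0.
        if not self.corrected_flag and self.window_label in ("SEW", "UEW", "TRUES"):
            floor = -1e-2 * max(float(self.counts.max()), 1.0)
            if self.counts.min() < floor:
                raise ValueError("uncorrected sinogram counts must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def with_counts(
        self, counts: np.ndarray, label: str | None = None, corrected: bool | None = None
    ) -> "Sinogram":
        return Sinogram(
            counts,
            self.geometry,
            self.window_label if label is None else label,
            self.corrected_flag if corrected is None else corrected,
        )

    def plane(self, view: int) -> np.ndarray:
        """The radial x axial projection plane of one view."""
        return self.counts[view]


@dataclass
class ActivityVolume:
    """Activity concentration (kBq/ml) on an (x, y, z) voxel grid."""

    values: np.ndarray
    voxel_size_cm: tuple[float, float, float]

    _allow_negative: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("volume must be 3D (x, y, z)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume values must be finite")
        if not self._allow_negative and self.values.min() < 0:
            raise ValueError("activity must be nonnegative")

    @property
    def voxel_volume_ml(self) -> float:
        dx, dy, dz = self.voxel_size_cm
        return dx * dy * dz

    def scaled(self, factor: float) -> "ActivityVolume":
        return replace(self, values=self.values * factor)


@dataclass
class MuMap(ActivityVolume):
    """511 keV linear attenuation coefficients (1/cm) on the shared grid.

    Water is ~0.096, skull ~0.15, lead ~1.75; anything above 2.0 is
    rejected as unphysical.
    """

    MU_WATER: float = field(default=0.096, repr=False)

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.values.max() > 2.0:
            raise ValueError("mu values above 2.0 /cm are unphysical at 511 keV")


def write_sinogram(path: str | Path, sino: Sinogram) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("counts", data=sino.counts)
        d.attrs["window_label"] = sino.window_label
        d.attrs["corrected_flag"] = bool(sino.corrected_flag)
        g = f.create_group("geometry")
        for name in _GEOM_FIELDS:
            g.attrs[name] = getattr(sino.geometry, name)


def read_sinogram(path: str | Path) -> Sinogram:
    with h5py.File(path, "r") as f:
        d = f["counts"]
        geom = ScannerGeometry(
            **{
                name: (int if name.startswith("n_") else float)(f["geometry"].attrs[name])
                for name in _GEOM_FIELDS
            }
        )
        return Sinogram(
            d[()],
            geom,
            str(d.attrs["window_label"]),
            bool(d.attrs["corrected_flag"]),
        )


def write_volume(path: str | Path, vol: ActivityVolume) -> None:
    affine = np.diag([10 * s for s in vol.voxel_size_cm] + [1.0])
    nib.save(nib.Nifti1Image(vol.values, affine), str(path))


def read_volume(path: str | Path, mu: bool = False) -> ActivityVolume:
    img = nib.load(str(path))
    vox = tuple(float(z) / 10.0 for z in img.header.get_zooms()[:3])
    values = np.asarray(img.dataobj, dtype=float)
    if mu:
        return MuMap(values, vox)
    # reconstructed images legitimately carry small negatives
    return ActivityVolume(values, vox, _allow_negative=True)
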