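"""Scanner and image-grid geometry.

All lengths are centimetres.  Sinograms are stacks of 2D parallel-beam
projections (one radial profile per view per axial slice); the image grid
shares the radial sampling so that the projector and FBP are an exactly
matched pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScannerGeometry"]


@dataclass(frozen=True)
class ScannerGeometry:
    """Parallel-beam geometry of a 2D-rebinned PET acquisition.

    Defaults mimic a 59-slice brain scanner with 2.6 mm slices and a
    2 mm transaxial sampling.  ``n_views`` views span [0, 180) degrees.
    """

    n_views: int = 96
    n_radial: int = 128
    radial_bin_cm: float = 0.2
    n_slices: int = 59
    slice_thickness_cm: float = 0.26
    fov_radius_cm: float = 12.8

    def __post_init__(self) -> None:
        for name in ("n_views", "n_radial", "n_slices"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("radial_bin_cm", "slice_thickness_cm", "fov_radius_cm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_radial * self.radial_bin_cm < 2 * self.fov_radius_cm - 1e-9:
            raise ValueError("radial extent must cover the transaxial FOV")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Sinogram array shape, (view, radial, slice)."""
        return (self.n_views, self.n_radial, self.n_slices)

    @property
    def view_angles_deg(self) -> np.ndarray:
        return np.arange(self.n_views) * 180.0 / self.n_views

    @property
    def radial_offsets_cm(self) -> np.ndarray:
        """Physical offset of each radial bin centre.

        Bin ``n_radial // 2`` sits on the scanner axis, matching the
        rotation centre used by the projector/FBP pair.
        """
        return (np.arange(self.n_radial) - self.n_radial // 2) * self.radial_bin_cm

    @property
    def slice_positions_cm(self) -> np.ndarray:
        return (np.arange(self.n_slices) + 0.5) * self.slice_thickness_cm

    @property
    def axial_extent_cm(self) -> float:
        return self.n_slices * self.slice_thickness_cm

    # -- image grid shared by phantoms and reconstructions ---------------

    @property
    def image_shape(self) -> tuple[int, int, int]:
        """(x, y, z) voxel grid matched to the sinogram sampling."""
        return (self.n_radial, self.n_radial, self.n_slices)

    @property
    def voxel_size_cm(self) -> tuple[float, float, float]:
        return (self.radial_bin_cm, self.radial_bin_cm, self.slice_thickness_cm)

    @property
    def voxel_volume_ml(self) -> float:
        dx, dy, dz = self.voxel_size_cm
        return dx * dy * dz

    def image_coords_cm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-centre coordinates (x, y, z) with the scanner axis at 0."""
        n = self.n_radial
        xy = (np.arange(n) - n // 2) * self.radial_bin_cm
        z = self.slice_positions_cm - self.axial_extent_cm / 2.0
        return xy, xy.copy(), z
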