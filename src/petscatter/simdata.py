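"""Synthetic acquisition model: phantoms, ground-truth scatter, prompts.

Every downstream stage (calibration, DEC/HDE correction, reconstruction,
quantification) is validated against data from this module because the
true scatter is known by construction — the situation clinical data can
never provide.

Two scatter generators are available:

``broad_gaussian``
    Scatter is a broad 2D Gaussian blur (radial x axial, per view) of the
    attenuation-weighted trues, renormalised so scattered/total counts
    equals the configured scatter fraction.  This deliberately does NOT
    follow the DEC kernel's functional form, so it exercises model
    mismatch the way a physical acquisition would.

``dec_self_consistent``
    Prompts satisfy the DEC fixed point p = t + k (*) p per view, solved
    in frequency space as P = T/(1 - S).  DEC with the true (alpha, beta)
    in circular mode then recovers the trues exactly, giving an algebraic
    ground truth for exactness and calibration-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft
from scipy.ndimage import gaussian_filter

from .containers import ActivityVolume, MuMap, Sinogram
from .geometry import ScannerGeometry
from .kernel import FrequencyGrid, KernelParams, kernel_response
from .project import forward_project, mu_line_integrals

__all__ = [
    "ScatterModelConfig",
    "WindowConfig",
    "build_phantom",
    "uniform_cylinder",
    "iec_like",
    "brain_phantom",
    "forward_project",
    "simulate_scatter",
    "compose_prompts",
    "LABELS",
]

MU_WATER = 0.096  # 1/cm at 511 keV
MU_SKULL = 0.151

LABELS = {"background": 0, "wm": 1, "gm": 2, "csf": 3, "skull": 4, "water": 5}

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class WindowConfig:
    """Relative true-coincidence efficiency of each energy window.

    The upper window (UEW) is a sub-range of the standard window (SEW),
    so it records fewer trues.
    """

    sew_true_efficiency: float = 0.9
    uew_true_efficiency: float = 0.3

    def __post_init__(self) -> None:
        for v in (self.sew_true_efficiency, self.uew_true_efficiency):
            if not (0 < v <= 1):
                raise ValueError("efficiencies must be in (0, 1]")
        if self.uew_true_efficiency > self.sew_true_efficiency:
            raise ValueError("UEW efficiency cannot exceed SEW efficiency")


@dataclass(frozen=True)
class ScatterModelConfig:
    """Ground-truth scatter generator settings.

    ``scatter_fraction_*`` are scattered/(scattered+true) count fractions
    per window; the upper window's must not exceed the standard window's.
    In ``dec_self_consistent`` mode the scatter shape and amount follow
    from the kernel parameters instead, and ``kernel_params`` (and, for
    dual-window studies, ``kernel_params_uew``) must be supplied.
    """

    scatter_fraction_sew: float = 0.35
    scatter_fraction_uew: float = 0.10
    blur_fwhm_radial_cm: float = 8.0
    blur_fwhm_axial_cm: float = 6.0
    attenuation_weighting: bool = True
    oof_background_amplitude: float = 0.0
    mode: str = "broad_gaussian"
    kernel_params: KernelParams | None = None
    kernel_params_uew: KernelParams | None = None

    def __post_init__(self) -> None:
        for v in (self.scatter_fraction_sew, self.scatter_fraction_uew):
            if not (0 <= v < 1):
                raise ValueError("scatter fractions must lie in [0, 1)")
        if self.scatter_fraction_uew > self.scatter_fraction_sew:
            raise ValueError("UEW scatter fraction must not exceed SEW's")
        if self.mode not in ("broad_gaussian", "dec_self_consistent"):
            raise ValueError(f"unknown scatter mode {self.mode!r}")
        if self.oof_background_amplitude < 0:
            raise ValueError("out-of-FOV amplitude must be >= 0")
        if self.mode == "dec_self_consistent" and self.kernel_params is None:
            raise ValueError("dec_self_consistent mode requires kernel_params")


# --------------------------------------------------------------------------
# phantoms
# --------------------------------------------------------------------------


def _grids(geometry: ScannerGeometry):
    x, y, z = geometry.image_coords_cm()
    return x[:, None, None], y[None, :, None], z[None, None, :]


def _finish(
    geometry: ScannerGeometry, activity: np.ndarray, mu: np.ndarray, labels: np.ndarray
):
    vox = geometry.voxel_size_cm
    return (
        ActivityVolume(activity, vox),
        MuMap(mu, vox),
        labels.astype(np.int16),
    )


def uniform_cylinder(
    geometry: ScannerGeometry,
    diameter_cm: float = 15.0,
    activity_kbq_ml: float = 10.0,
    mu_value: float = MU_WATER,
    length_cm: float | None = None,
):
    """Water-filled uniform cylinder, centred on the scanner axis."""
    r = diameter_cm / 2.0
    if r > geometry.fov_radius_cm:
        raise ValueError("cylinder does not fit inside the transaxial FOV")
    if activity_kbq_ml < 0:
        raise ValueError("activity must be nonnegative")
    X, Y, Z = _grids(geometry)
    inside = (X**2 + Y**2 <= r**2)
    if length_cm is not None:
        inside = inside & (np.abs(Z) <= length_cm / 2.0)
    else:
        inside = np.broadcast_to(inside, geometry.image_shape)
    activity = np.where(inside, activity_kbq_ml, 0.0)
    mu = np.where(inside, mu_value, 0.0)
    labels = np.where(inside, LABELS["water"], 0)
    return _finish(geometry, activity, mu, labels)


def iec_like(
    geometry: ScannerGeometry,
    semi_axes_cm: tuple[float, float] = (15.0, 11.0),
    activity_kbq_ml: float = 10.0,
    mu_value: float = MU_WATER,
    length_cm: float | None = None,
):
    """Elliptical body-phantom surrogate (uniform elliptical cylinder)."""
    a, b = semi_axes_cm
    if max(a, b) > geometry.fov_radius_cm:
        raise ValueError("ellipse does not fit inside the transaxial FOV")
    if activity_kbq_ml < 0:
        raise ValueError("activity must be nonnegative")
    X, Y, Z = _grids(geometry)
    inside = (X / a) ** 2 + (Y / b) ** 2 <= 1.0
    if length_cm is not None:
        inside = inside & (np.abs(Z) <= length_cm / 2.0)
    else:
        inside = np.broadcast_to(inside, geometry.image_shape)
    activity = np.where(inside, activity_kbq_ml, 0.0)
    mu = np.where(inside, mu_value, 0.0)
    labels = np.where(inside, LABELS["water"], 0)
    return _finish(geometry, activity, mu, labels)


def brain_phantom(
    geometry: ScannerGeometry,
    gm_activity_kbq_ml: float = 40.0,
    gm_wm_ratio: float = 4.0,
    scale: float = 1.0,
):
    """Three nested ellipsoids: GM shell around a WM core, a CSF rim, and
    a thin higher-mu skull shell.

    Default activities follow the ~4:1 grey-to-white contrast of cerebral
    blood flow; CSF is cold.  ``scale`` shrinks/grows all semi-axes
    together (used to jitter 'subjects').
    """
    if gm_activity_kbq_ml < 0 or gm_wm_ratio <= 0:
        raise ValueError("activities must be nonnegative and ratio positive")
    axes = {
        "skull_outer": (8.4, 9.4, 7.4),
        "skull_inner": (8.0, 9.0, 7.0),
        "gm_outer": (7.5, 8.5, 6.6),
        "wm_core": (5.0, 6.0, 4.4),
    }
    axes = {k: tuple(scale * s for s in v) for k, v in axes.items()}
    if max(axes["skull_outer"][:2]) > geometry.fov_radius_cm:
        raise ValueError("head phantom does not fit inside the transaxial FOV")
    X, Y, Z = _grids(geometry)

    def inside(sa):
        return (X / sa[0]) ** 2 + (Y / sa[1]) ** 2 + (Z / sa[2]) ** 2 <= 1.0

    in_sk_o, in_sk_i = inside(axes["skull_outer"]), inside(axes["skull_inner"])
    in_gm_o, in_wm = inside(axes["gm_outer"]), inside(axes["wm_core"])

    labels = np.zeros(geometry.image_shape, dtype=np.int16)
    labels[in_sk_o & ~in_sk_i] = LABELS["skull"]
    labels[in_sk_i & ~in_gm_o] = LABELS["csf"]
    labels[in_gm_o & ~in_wm] = LABELS["gm"]
    labels[in_wm] = LABELS["wm"]

    activity = np.zeros(geometry.image_shape)
    activity[labels == LABELS["gm"]] = gm_activity_kbq_ml
    activity[labels == LABELS["wm"]] = gm_activity_kbq_ml / gm_wm_ratio

    mu = np.zeros(geometry.image_shape)
    mu[labels > 0] = MU_WATER
    mu[labels == LABELS["skull"]] = MU_SKULL
    return _finish(geometry, activity, mu, labels)


_SHAPES = {
    "uniform_cylinder": uniform_cylinder,
    "iec_like": iec_like,
    "brain": brain_phantom,
}


def build_phantom(spec: dict, geometry: ScannerGeometry):
    """Build (ActivityVolume, MuMap, labels) from a phantom descriptor.

    ``spec`` is a mapping with a ``shape`` key naming one of
    ``uniform_cylinder``, ``iec_like`` or ``brain``; remaining keys are
    forwarded to the shape builder.
    """
    spec = dict(spec)
    try:
        shape = spec.pop("shape")
    except KeyError:
        raise ValueError("phantom spec needs a 'shape' entry") from None
    if shape not in _SHAPES:
        raise ValueError(f"unsupported phantom shape {shape!r}")
    return _SHAPES[shape](geometry, **spec)


# --------------------------------------------------------------------------
# scatter and prompts
# --------------------------------------------------------------------------


def _self_consistent_prompts(
    trues: np.ndarray, geometry: ScannerGeometry, params: KernelParams
) -> np.ndarray:
    """Solve p = t + k (*) p per view plane in frequency space (circular)."""
    spacing = (geometry.radial_bin_cm, geometry.slice_thickness_cm)
    grid = FrequencyGrid((geometry.n_radial, geometry.n_slices), spacing)
    resp = kernel_response(params, grid)
    if resp.max() >= 1.0:
        raise ValueError("kernel response must stay below 1 for the fixed point")
    prompts = np.empty_like(trues)
    for v in range(trues.shape[0]):
        spec = sp_fft.fft2(trues[v])
        prompts[v] = sp_fft.ifft2(spec / (1.0 - resp)).real
    return prompts


def simulate_scatter(
    trues: Sinogram, mu: MuMap | None, cfg: ScatterModelConfig
) -> Sinogram:
    """Ground-truth scatter sinogram for the standard window.

    In ``broad_gaussian`` mode, sum(scatter)/(sum(scatter)+sum(trues))
    equals the configured SEW scatter fraction exactly (before any
    out-of-FOV background is added).
    """
    geom = trues.geometry
    t = trues.counts
    if t.min() < 0:
        raise ValueError("trues must be nonnegative")

    if cfg.mode == "dec_self_consistent":
        # signed on purpose: the FFT fixed point rings ~1e-4 negative at
        # the support edge, and clipping would break DEC exactness
        prompts = _self_consistent_prompts(t, geom, cfg.kernel_params)
        scatter = prompts - t
        if scatter.min() < -1e-2 * max(scatter.max(), 1.0):
            raise ValueError("self-consistent scatter came out significantly negative")
    else:
        sf = cfg.scatter_fraction_sew
        if sf == 0:
            scatter = np.zeros_like(t)
        else:
            base = t
            if cfg.attenuation_weighting and mu is not None:
                aline = mu_line_integrals(mu, geom)
                base = t * (1.0 - np.exp(-aline))
            sig_r = cfg.blur_fwhm_radial_cm * _FWHM_TO_SIGMA / geom.radial_bin_cm
            sig_z = cfg.blur_fwhm_axial_cm * _FWHM_TO_SIGMA / geom.slice_thickness_cm
            scatter = gaussian_filter(base, sigma=(0.0, sig_r, sig_z), mode="constant")
            total = scatter.sum()
            if total <= 0:
                raise ValueError("cannot normalise scatter of an empty sinogram")
            scatter *= (sf / (1.0 - sf)) * t.sum() / total

    if cfg.oof_background_amplitude > 0:
        z = np.arange(geom.n_slices)
        ramp = np.clip(1.0 - z / max(geom.n_slices / 2.0, 1.0), 0.0, None)
        scatter = scatter + cfg.oof_background_amplitude * ramp[None, None, :]

    return trues.with_counts(scatter, label="SCATTER")


def compose_prompts(
    trues: Sinogram,
    scatter: Sinogram,
    win: WindowConfig,
    cfg: ScatterModelConfig,
    seed: int | None = None,
) -> tuple[Sinogram, Sinogram]:
    """Assemble SEW and UEW prompt sinograms from trues and SEW scatter.

    Noiseless composition is ``window = efficiency * trues + window
    scatter``.  The UEW scatter is the SEW scatter rescaled to the (small)
    UEW scatter fraction — except in ``dec_self_consistent`` mode with a
    UEW kernel configured, where the UEW prompts are generated from their
    own fixed point so the hybrid reference correction is exact.  With a
    seed, both windows are Poisson-sampled reproducibly.
    """
    if trues.counts.shape != scatter.counts.shape:
        raise ValueError("trues and scatter shapes differ")
    geom = trues.geometry
    if cfg.mode == "dec_self_consistent":
        # the fixed point is linear in the trues, so the window's scatter
        # scales with its true efficiency: sew = e*t/(1-S) = e*(t + s)
        sew = win.sew_true_efficiency * (trues.counts + scatter.counts)
    else:
        sew = win.sew_true_efficiency * trues.counts + scatter.counts

    uew_trues = win.uew_true_efficiency * trues.counts
    if cfg.mode == "dec_self_consistent" and cfg.kernel_params_uew is not None:
        uew = _self_consistent_prompts(uew_trues, geom, cfg.kernel_params_uew)
    else:
        sf = cfg.scatter_fraction_uew
        stot = scatter.counts.sum()
        if sf > 0 and stot > 0:
            target = sf / (1.0 - sf) * uew_trues.sum()
            uew = uew_trues + scatter.counts * (target / stot)
        else:
            uew = uew_trues

    if seed is not None:
        rng = np.random.default_rng(seed)
        sew = rng.poisson(np.clip(sew, 0.0, None)).astype(float)
        uew = rng.poisson(np.clip(uew, 0.0, None)).astype(float)

    return (
        Sinogram(sew, geom, window_label="SEW"),
        Sinogram(uew, geom, window_label="UEW"),
    )
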