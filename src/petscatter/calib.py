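"""Phantom calibration of the scatter kernel by tail matching.

Outside the attenuating object's projected support, an emission sinogram
contains scatter only, so the kernel parameters (alpha, beta) are fitted
per calibration phantom by least squares between a model prediction and
the measured counts over those tail bins, and the per-phantom fits are
assembled into an object-volume-indexed table.

Naively convolving the measured sinogram and comparing it with itself on
the tail is degenerate: a near-identity kernel reproduces tail counts
from themselves perfectly.  The fit therefore predicts the tail from a
trues model passed through the convolution fixed point p = t/(1 - S):

* template objective (recommended for phantoms): the trues shape is known
  up to amplitude — the unit-activity attenuated projection of the
  segmented phantom.  The amplitude is fitted linearly on the high-count
  support bins; (alpha, beta) are fitted on the tail residuals.  Noise
  enters only the target, so the estimate is unbiased.
* self-consistent objective (no template): trues are estimated as
  (p - k (*) p) restricted to the support and re-predicted through
  1/(1 - S).  Exact in the noiseless limit but noise-sensitive, since
  support noise propagates through the fixed-point amplification.

The optimiser is fully deterministic: a log-spaced grid scan followed by
Nelder-Mead refinement started from the best few well-separated cells
(the objective has narrow basins; a single start can stall elsewhere).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft
from scipy.ndimage import binary_dilation
from scipy.optimize import minimize

from .containers import MuMap, Sinogram
from .deccor import CalibrationTable
from .geometry import ScannerGeometry
from .kernel import FrequencyGrid, KernelParams, kernel_response
from .project import mu_line_integrals

__all__ = [
    "TailMask",
    "FitDiagnostics",
    "tail_mask",
    "fit_kernel_params",
    "build_calibration_table",
]

DEFAULT_ALPHA_BOUNDS = (0.01, 10.0)
DEFAULT_BETA_BOUNDS = (0.01, 50.0)  # cm^2


@dataclass(frozen=True)
class TailMask:
    """Boolean sinogram mask of scatter-only bins (True = tail)."""

    mask: np.ndarray
    margin_bins: int

    def __post_init__(self) -> None:
        if self.mask.dtype != bool:
            raise TypeError("tail mask must be boolean")
        if not self.mask.any():
            raise ValueError("tail mask is empty (object fills the FOV)")

    @property
    def n_bins(self) -> int:
        return int(self.mask.sum())

    @property
    def plane_mask(self) -> np.ndarray:
        """Bins that are tail in every view (radial x axial plane)."""
        return self.mask.all(axis=0)


@dataclass(frozen=True)
class FitDiagnostics:
    objective: float
    at_bound: bool
    n_tail_bins: int
    grid_best: tuple[float, float]
    amplitude: float | None = None


def tail_mask(
    mu: MuMap,
    geometry: ScannerGeometry,
    margin_bins: int = 2,
    eps_support: float = 1e-3,
) -> TailMask:
    """Bins outside the object's projected support, with a safety margin.

    A bin belongs to the tail iff its attenuation line integral is below
    ``eps_support`` and it is at least ``margin_bins`` radial bins away
    from any support bin.  Derived from the mu map's projection: robust to
    emission noise, and the transmission image always exists in the
    correction chain.
    """
    if margin_bins < 0:
        raise ValueError("margin_bins must be >= 0")
    aline = mu_line_integrals(mu, geometry)
    support = aline >= eps_support
    if margin_bins > 0:
        # dilate along the radial axis only
        structure = np.zeros((1, 3, 1), dtype=bool)
        structure[0, :, 0] = True
        support = binary_dilation(support, structure=structure, iterations=margin_bins)
    return TailMask(~support, margin_bins)


def _work_shape(plane_shape: tuple[int, int], mode: str) -> tuple[int, int]:
    if mode == "circular":
        return plane_shape
    if mode == "zeropad":
        return tuple(sp_fft.next_fast_len(2 * n) for n in plane_shape)
    raise ValueError(f"unknown convolution mode {mode!r}")


def _template_objective(
    stack: np.ndarray,
    template: np.ndarray,
    m: np.ndarray,
    spacing: tuple[float, float],
    mode: str,
    weights: np.ndarray | None,
):
    """Objective with known trues shape: h = template/(1-S), amplitude from
    support bins, residuals over tail bins.  ``stack`` is (plane, r, z)."""
    shape = stack.shape[1:]
    work = _work_shape(shape, mode)
    grid = FrequencyGrid(work, spacing)
    th = sp_fft.fft2(template, s=work, axes=(1, 2))
    sup = ~m
    target = stack[m]
    p_sup = stack[sup]
    w = 1.0 if weights is None else weights

    def objective(alpha: float, beta: float):
        resp = kernel_response(KernelParams(alpha, beta), grid)
        h = sp_fft.ifft2(th / (1.0 - resp[None]), axes=(1, 2)).real
        h = h[:, : shape[0], : shape[1]]
        denom = float((h[sup] ** 2).sum())
        c = float((p_sup * h[sup]).sum() / denom) if denom > 0 else 0.0
        r = c * h[m] - target
        return float(np.sum(w * r * r)), c

    return objective


def _self_consistent_objective(
    stack: np.ndarray,
    m: np.ndarray,
    spacing: tuple[float, float],
    mode: str,
    weights: np.ndarray | None,
):
    """Data-driven objective: trues estimated on the support from the DEC
    residual, then re-predicted through the fixed point."""
    shape = stack.shape[1:]
    work = _work_shape(shape, mode)
    grid = FrequencyGrid(work, spacing)
    ph = sp_fft.fft2(stack, s=work, axes=(1, 2))
    sup = (~m).astype(float)
    target = stack[m]
    w = 1.0 if weights is None else weights

    def objective(alpha: float, beta: float):
        resp = kernel_response(KernelParams(alpha, beta), grid)
        est = sp_fft.ifft2(ph * resp[None], axes=(1, 2)).real
        est = est[:, : shape[0], : shape[1]]
        t_hat = np.clip(stack - est, 0.0, None) * sup
        pmod = sp_fft.ifft2(
            sp_fft.fft2(t_hat, s=work, axes=(1, 2)) / (1.0 - resp[None]), axes=(1, 2)
        ).real
        r = pmod[:, : shape[0], : shape[1]][m] - target
        return float(np.sum(w * r * r)), None

    return objective


def _grid_then_refine(objective, alpha_bounds, beta_bounds, grid_density, n_starts=6):
    la = np.linspace(np.log(alpha_bounds[0]), np.log(alpha_bounds[1]), grid_density)
    lb = np.linspace(np.log(beta_bounds[0]), np.log(beta_bounds[1]), grid_density)
    M = np.empty((len(la), len(lb)))
    for i, A in enumerate(la):
        for j, B in enumerate(lb):
            M[i, j], _ = objective(np.exp(A), np.exp(B))
    order = np.argsort(M.ravel())
    starts, taken = [], []
    for idx in order:
        i, j = divmod(int(idx), len(lb))
        if all(abs(i - i0) >= 3 or abs(j - j0) >= 3 for i0, j0 in taken):
            taken.append((i, j))
            starts.append((la[i], lb[j]))
        if len(starts) == n_starts:
            break
    i0, j0 = taken[0]
    grid_best = (float(np.exp(la[i0])), float(np.exp(lb[j0])))

    best_val, best_x = np.inf, np.array(starts[0])
    for s in starts:
        res = minimize(
            lambda x: objective(np.exp(x[0]), np.exp(x[1]))[0],
            x0=np.asarray(s),
            method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-16, "maxiter": 400},
        )
        if res.fun < best_val:
            best_val, best_x = float(res.fun), res.x
    return best_x, best_val, grid_best


def fit_kernel_params(
    prompts: Sinogram,
    mask: TailMask,
    template: Sinogram | np.ndarray | None = None,
    alpha_bounds: tuple[float, float] = DEFAULT_ALPHA_BOUNDS,
    beta_bounds: tuple[float, float] = DEFAULT_BETA_BOUNDS,
    grid_density: int = 40,
    mode: str = "zeropad",
    poisson_weighting: bool = False,
    average_views: bool = True,
) -> tuple[KernelParams, FitDiagnostics]:
    """Fit (alpha, beta) by matching the predicted scatter to the tails.

    ``template`` is the unit-amplitude trues model of the calibration
    phantom (its attenuated projection); when given, the noise-robust
    template objective is used, otherwise the self-consistent data-driven
    one.  ``average_views`` collapses the view axis first — exact for any
    phantom by linearity of the fixed point, and it suppresses noise.
    Deterministic; returns the parameters and fit diagnostics.
    """
    counts = prompts.counts
    if counts.min() < -1e-2 * max(float(counts.max()), 1.0):
        raise ValueError("prompts must be nonnegative")
    geom = prompts.geometry
    spacing = (geom.radial_bin_cm, geom.slice_thickness_cm)

    tmpl = template.counts if isinstance(template, Sinogram) else template
    if average_views:
        stack = counts.mean(axis=0)[None]
        m = mask.plane_mask[None]
        tstack = tmpl.mean(axis=0)[None] if tmpl is not None else None
    else:
        stack = counts
        m = mask.mask
        tstack = tmpl

    if not m.any():
        raise ValueError("tail mask is empty")
    if stack[m].sum() <= 0:
        raise ValueError("tail counts are all zero; nothing to fit")

    weights = 1.0 / np.maximum(stack[m], 1.0) if poisson_weighting else None

    if tstack is not None:
        objective = _template_objective(stack, tstack, m, spacing, mode, weights)
    else:
        objective = _self_consistent_objective(stack, m, spacing, mode, weights)

    best_x, best_val, grid_best = _grid_then_refine(
        objective, alpha_bounds, beta_bounds, grid_density
    )
    lax = float(np.clip(best_x[0], np.log(alpha_bounds[0]), np.log(alpha_bounds[1])))
    lbx = float(np.clip(best_x[1], np.log(beta_bounds[0]), np.log(beta_bounds[1])))
    alpha, beta = float(np.exp(lax)), float(np.exp(lbx))

    rtol = 1e-3
    at_bound = any(
        abs(np.log(v) - np.log(b)) < rtol
        for v, bnds in ((alpha, alpha_bounds), (beta, beta_bounds))
        for b in bnds
    )
    final_val, amplitude = objective(alpha, beta)
    params = KernelParams(alpha, beta)
    diag = FitDiagnostics(
        objective=final_val,
        at_bound=at_bound,
        n_tail_bins=int(m.sum()),
        grid_best=grid_best,
        amplitude=amplitude,
    )
    return params, diag


def build_calibration_table(
    fits: list[tuple[float, KernelParams]]
) -> CalibrationTable:
    """Assemble per-phantom fits into a volume-sorted calibration table."""
    if not fits:
        raise ValueError("at least one fit is required")
    volumes = [v for v, _ in fits]
    if len(set(volumes)) != len(volumes):
        raise ValueError("duplicate object volumes in calibration fits")
    order = np.argsort(volumes)
    return CalibrationTable(
        tuple(float(volumes[i]) for i in order),
        tuple(fits[i][1] for i in order),
    )
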