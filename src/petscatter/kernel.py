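"""The empirical scatter kernel and its application by convolution.

The kernel is a low-pass filter acting on the radial x axial projection
plane of each view,

    S(f) = 1 / (1 + alpha * exp(beta * |f|^2)),

with ``f`` the 2D spatial frequency in cycles/cm and |f| Euclidean.
``alpha`` sets the amplitude (the DC gain is 1/(1+alpha), the fraction of
total counts attributed to scatter) and ``beta`` (cm^2) sets the width of
the scatter tails.  Frequencies are physical, computed from the radial bin
and slice spacings, so a fitted (alpha, beta) transfers across sinogram
sizes and anisotropic sampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import fft as sp_fft

__all__ = [
    "KernelParams",
    "FrequencyGrid",
    "kernel_response",
    "scatter_convolve",
    "dc_gain",
]


@dataclass(frozen=True)
class KernelParams:
    """(alpha, beta) parameter pair of one scatter kernel.

    alpha is dimensionless and > 0; beta is in cm^2 and >= 0.
    """

    alpha: float
    beta_cm2: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError("alpha must be finite and > 0")
        if not (np.isfinite(self.beta_cm2) and self.beta_cm2 >= 0):
            raise ValueError("beta must be finite and >= 0")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"alpha": self.alpha, "beta_cm2": self.beta_cm2})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "KernelParams":
        d = json.loads(Path(path).read_text())
        return cls(float(d["alpha"]), float(d["beta_cm2"]))


@dataclass(frozen=True)
class FrequencyGrid:
    """FFT-layout frequency coordinates of a (radial, axial) plane."""

    shape: tuple[int, int]
    spacing_cm: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 2 or any(n < 1 for n in self.shape):
            raise ValueError("plane shape must be two positive integers")
        if any(not d > 0 for d in self.spacing_cm):
            raise ValueError("spacings must be positive")

    @property
    def freqs_cycles_per_cm(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.fft.fftfreq(self.shape[0], d=self.spacing_cm[0]),
            np.fft.fftfreq(self.shape[1], d=self.spacing_cm[1]),
        )

    @property
    def freq_sq(self) -> np.ndarray:
        """|f|^2 on the full 2D grid, cycles^2/cm^2."""
        fr, fz = self.freqs_cycles_per_cm
        return fr[:, None] ** 2 + fz[None, :] ** 2


def kernel_response(params: KernelParams, grid: FrequencyGrid) -> np.ndarray:
    """Evaluate S(f) = 1/(1 + alpha exp(beta |f|^2)) on a frequency grid.

    Computed in log space so large beta*|f|^2 underflows gracefully to 0
    instead of overflowing; the result is real and lies in (0, 1/(1+alpha)].
    """
    x = np.log(params.alpha) + params.beta_cm2 * grid.freq_sq
    return np.exp(-np.logaddexp(0.0, x))


def dc_gain(params: KernelParams) -> float:
    """S at f = 0: the fraction of total counts the kernel calls scatter."""
    return 1.0 / (1.0 + params.alpha)


def _padded_shape(shape: tuple[int, int]) -> tuple[int, int]:
    return tuple(sp_fft.next_fast_len(2 * n) for n in shape)


def scatter_convolve(
    plane: np.ndarray,
    params: KernelParams,
    spacing_cm: tuple[float, float],
    mode: str = "zeropad",
) -> np.ndarray:
    """Convolve one radial x axial plane with the scatter kernel.

    ``zeropad`` pads each axis to >= 2x its size before the FFT and crops
    back, approximating linear convolution so scatter tails do not wrap
    around the FOV edge.  ``circular`` applies the kernel on the native
    grid; it is exact for the self-consistent simulation mode and obeys
    sum(out) = dc_gain * sum(in) identically.
    """
    plane = np.asarray(plane, dtype=float)
    if plane.ndim != 2:
        raise ValueError("plane must be 2D (radial, axial)")
    if not np.all(np.isfinite(plane)):
        raise ValueError("plane must be finite")
    if mode == "circular":
        work_shape = plane.shape
    elif mode == "zeropad":
        work_shape = _padded_shape(plane.shape)
    else:
        raise ValueError(f"unknown convolution mode {mode!r}")
    grid = FrequencyGrid(work_shape, tuple(spacing_cm))
    resp = kernel_response(params, grid)
    spec = sp_fft.fft2(plane, s=work_shape)
    out = sp_fft.ifft2(spec * resp).real
    return out[: plane.shape[0], : plane.shape[1]]


def spatial_kernel(
    params: KernelParams, shape: tuple[int, int], spacing_cm: tuple[float, float]
) -> np.ndarray:
    """The real-space kernel (centred at index (0, 0), FFT layout)."""
    grid = FrequencyGrid(tuple(shape), tuple(spacing_cm))
    k = sp_fft.ifft2(kernel_response(params, grid))
    return k.real
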