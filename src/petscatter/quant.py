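"""Oxygen-15 quantification: CBF, CBV, OEF and CMRO2.

The estimators share their forward models with the synthetic-data path so
every inversion is testable as an exact round trip:

* CBF — autoradiographic method on the H2(15)O scan: the one-compartment
  Kety model dCt/dt = K1*Ca(t) - k2*Ct with K1 = f*rho/6000 (per second,
  f in ml/100g/min) and k2 = f/(6000*p); accumulated tissue counts
  A(f) = integral of Ct over the scan are inverted by monotone table
  lookup.
* CBV — C(15)O ratio method: CBV = 100 * C_pet / (rho * R_sl * C_blood).
* OEF / CMRO2 — simplified (15)O2 model, linear in OEF:
  A_O2 = OEF * A_w(f) + V_B * integral(Ca_O2), with A_w the same
  one-compartment accumulation operator and V_B = CBV*rho*R_sl/100 the
  intravascular term; CMRO2 = OEF * CBF * CaO2.  Recirculating water of
  metabolism is deliberately omitted (documented simplification).

All curve math operates on decay-corrected activities; the 15O decay
constant is exposed only for converting measured curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LAMBDA_O15_PER_S",
    "TimeActivityCurve",
    "QuantConstants",
    "synth_aif",
    "h2o_tissue_counts",
    "cbf_autoradiographic",
    "cbv_from_co",
    "oef_cmro2",
]

#: ln 2 / 122.24 s half-life of 15O
LAMBDA_O15_PER_S = np.log(2.0) / 122.24

#: fixed integration step for all kinetic integrals, seconds
DT_S = 0.5


@dataclass(frozen=True)
class TimeActivityCurve:
    """Sampled activity concentration (kBq/ml) versus time (s)."""

    times_s: np.ndarray
    values_kbq_ml: np.ndarray
    decay_corrected: bool = True

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        v = np.asarray(self.values_kbq_ml, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "values_kbq_ml", v)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be matching 1D arrays")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if v.min() < 0:
            raise ValueError("activities must be nonnegative")

    def decay_correct(self, reference_time_s: float = 0.0) -> "TimeActivityCurve":
        """Remove physical 15O decay relative to a reference time."""
        if self.decay_corrected:
            return self
        v = self.values_kbq_ml * np.exp(
            LAMBDA_O15_PER_S * (self.times_s - reference_time_s)
        )
        return TimeActivityCurve(self.times_s, v, decay_corrected=True)

    def resampled(self, dt_s: float = DT_S, t_end_s: float | None = None):
        """(t, v) on the fixed integration grid, linear interpolation."""
        t_end = self.times_s[-1] if t_end_s is None else t_end_s
        t = np.arange(0.0, t_end + dt_s / 2, dt_s)
        v = np.interp(t, self.times_s, self.values_kbq_ml, left=0.0, right=0.0)
        return t, v

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"time_s": self.times_s, "kbq_per_ml": self.values_kbq_ml}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TimeActivityCurve":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(), df["kbq_per_ml"].to_numpy())


@dataclass(frozen=True)
class QuantConstants:
    """Physiological constants of the quantification chain.

    p: water partition coefficient (ml/g); rho: brain density (g/ml);
    R_sl: small-to-large vessel hematocrit ratio; CaO2: arterial oxygen
    content (ml O2 / ml blood).  Literature defaults; all positive.
    """

    p_ml_g: float = 0.8
    rho_g_ml: float = 1.04
    r_small_large: float = 0.85
    cao2_ml_ml: float = 0.19

    def __post_init__(self) -> None:
        for name in ("p_ml_g", "rho_g_ml", "r_small_large", "cao2_ml_ml"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def synth_aif(
    amplitude: float = 30.0,
    t0_s: float = 10.0,
    gamma: float = 3.0,
    tau_s: float = 12.0,
    duration_s: float = 180.0,
    dt_s: float = DT_S,
) -> TimeActivityCurve:
    """Gamma-variate arterial input function (decay-corrected).

    Ca(t) = A * (t - t0)^gamma * exp(-(t - t0)/tau) for t > t0, else 0;
    the curve peaks at t0 + gamma*tau.  The default peaks near 45 s at
    roughly bolus-injection levels.
    """
    if amplitude <= 0 or tau_s <= 0:
        raise ValueError("amplitude and tau must be positive")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    dtp = np.clip(t - t0_s, 0.0, None)
    v = amplitude * dtp**gamma * np.exp(-dtp / tau_s)
    v[t <= t0_s] = 0.0
    return TimeActivityCurve(t, v, decay_corrected=True)


def _kety_rates(f: float, const: QuantConstants) -> tuple[float, float]:
    """K1 (1/s, per ml tissue) and k2 (1/s) for f in ml/100g/min."""
    k1 = f * const.rho_g_ml / 6000.0
    k2 = f / (6000.0 * const.p_ml_g)
    return k1, k2


def _one_compartment_accumulation(
    f: float, aif: TimeActivityCurve, const: QuantConstants, scan_length_s: float
) -> float:
    """Accumulated tissue counts A = integral_0^T Ct dt of the Kety model.

    Exponential-update integration: exact for piecewise-constant input, so
    the constant-input steady state Ct -> p*rho*Ca is reproduced exactly.
    """
    if f < 0:
        raise ValueError("flow must be nonnegative")
    if f == 0:
        return 0.0
    k1, k2 = _kety_rates(f, const)
    t, ca = aif.resampled(DT_S, scan_length_s)
    e = np.exp(-k2 * DT_S)
    ct = 0.0
    area = 0.0
    for i in range(len(t) - 1):
        ca_mid = 0.5 * (ca[i] + ca[i + 1])
        ct_next = ct * e + (k1 / k2) * (1.0 - e) * ca_mid
        area += 0.5 * (ct + ct_next) * DT_S
        ct = ct_next
    return float(area)


def h2o_tissue_counts(
    f: float | np.ndarray,
    aif: TimeActivityCurve,
    const: QuantConstants = QuantConstants(),
    scan_length_s: float = 180.0,
) -> float | np.ndarray:
    """Forward autoradiographic model: accumulated counts at flow f.

    Monotone increasing in f over the physiological range for bolus-like
    inputs, which is what makes table inversion well posed.
    """
    if not aif.decay_corrected:
        raise ValueError("AIF must be decay-corrected")
    if np.isscalar(f) or np.ndim(f) == 0:
        return _one_compartment_accumulation(float(f), aif, const, scan_length_s)
    fs = np.asarray(f, dtype=float)
    return np.array(
        [_one_compartment_accumulation(float(x), aif, const, scan_length_s) for x in fs]
    )


def cbf_autoradiographic(
    accumulated: np.ndarray,
    aif: TimeActivityCurve,
    const: QuantConstants = QuantConstants(),
    scan_length_s: float = 180.0,
    f_grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Invert accumulated H2O counts to CBF by monotone table lookup.

    Returns (cbf map in ml/100g/min, flag map); flagged voxels had counts
    above the table maximum and are clamped to the top of the grid.
    """
    if f_grid is None:
        f_grid = np.arange(0.0, 160.0 + 1e-9, 0.5)
    table = h2o_tissue_counts(f_grid, aif, const, scan_length_s)
    if np.any(np.diff(table) <= 0):
        raise ValueError("forward table is not strictly increasing; bad AIF or grid")
    a = np.asarray(accumulated, dtype=float)
    flags = a > table[-1]
    cbf = np.interp(np.clip(a, 0.0, table[-1]), table, f_grid)
    return cbf, flags


def cbv_from_co(
    c_pet: float | np.ndarray,
    c_blood: float,
    const: QuantConstants = QuantConstants(),
) -> float | np.ndarray:
    """CBV (ml/100g) from the CO scan: 100*C_pet/(rho*R_sl*C_blood)."""
    if c_blood <= 0:
        raise ValueError("blood activity must be positive")
    return 100.0 * np.asarray(c_pet, dtype=float) / (
        const.rho_g_ml * const.r_small_large * c_blood
    )


def co_tissue_activity(
    cbv: float | np.ndarray, c_blood: float, const: QuantConstants = QuantConstants()
) -> float | np.ndarray:
    """Forward CO model (inverse of :func:`cbv_from_co`)."""
    return np.asarray(cbv, dtype=float) * const.rho_g_ml * const.r_small_large * c_blood / 100.0


def o2_tissue_counts(
    oef: float | np.ndarray,
    f: float | np.ndarray,
    cbv: float | np.ndarray,
    aif_o2: TimeActivityCurve,
    const: QuantConstants = QuantConstants(),
    scan_length_s: float = 180.0,
) -> np.ndarray:
    """Forward O2 model: extraction term linear in OEF plus blood-borne term."""
    f = np.asarray(f, dtype=float)
    if f.ndim <= 1:
        a_w = np.asarray(h2o_tissue_counts(f, aif_o2, const, scan_length_s))
    else:
        grid = np.arange(0.0, max(160.0, float(f.max())) + 1e-9, 0.5)
        table = np.asarray(h2o_tissue_counts(grid, aif_o2, const, scan_length_s))
        a_w = np.interp(f, grid, table)
    t, ca = aif_o2.resampled(DT_S, scan_length_s)
    integral_ca = np.trapezoid(ca, t)
    v_b = np.asarray(cbv, dtype=float) * const.rho_g_ml * const.r_small_large / 100.0
    return np.asarray(oef, dtype=float) * a_w + v_b * integral_ca


def oef_cmro2(
    accumulated_o2: np.ndarray,
    f_map: np.ndarray,
    cbv_map: np.ndarray,
    aif_o2: TimeActivityCurve,
    const: QuantConstants = QuantConstants(),
    scan_length_s: float = 180.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel linear solve for OEF, then CMRO2 = OEF * CBF * CaO2.

    Returns (OEF, CMRO2 in ml O2/100g/min, flag map).  OEF is clipped to
    [0, 1.5]; voxels with no extraction sensitivity (f = 0) or clipped
    values are flagged.
    """
    a_o2 = np.asarray(accumulated_o2, dtype=float)
    f = np.asarray(f_map, dtype=float)
    cbv = np.asarray(cbv_map, dtype=float)

    # evaluate the accumulation operator on a dense flow grid once, then
    # interpolate: cheap and accurate (the table is smooth and monotone)
    grid = np.arange(0.0, max(160.0, float(f.max()) if f.size else 0.0) + 1e-9, 0.5)
    table = np.asarray(h2o_tissue_counts(grid, aif_o2, const, scan_length_s))
    a_w = np.interp(f, grid, table)

    t, ca = aif_o2.resampled(DT_S, scan_length_s)
    integral_ca = np.trapezoid(ca, t)
    v_b = cbv * const.rho_g_ml * const.r_small_large / 100.0

    flags = a_w <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        oef = np.where(flags, 0.0, (a_o2 - v_b * integral_ca) / np.where(flags, 1.0, a_w))
    clipped = (oef < 0.0) | (oef > 1.5)
    oef = np.clip(oef, 0.0, 1.5)
    cmro2 = oef * f * const.cao2_ml_ml
    return oef, cmro2, flags | clipped
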