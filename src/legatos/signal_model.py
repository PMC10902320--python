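"""Spoiled gradient-echo (SPGR) signal physics.

Forward steady-state signal, variable-flip-angle (VFA) estimation of the
native longitudinal relaxation rate R1_0 and equilibrium signal M0, and the
bidirectional conversion between signal intensity (SI) and gadolinium
concentration through the linear relaxivity model R1(t) = R1_0 + r1*C(t).

T2*/TE decay is neglected throughout: the dynamic protocols this package
targets use sub-millisecond echo times, where the TE-dependent attenuation
is a constant factor absorbed into M0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionParams",
    "RelaxationState",
    "ContrastAgentSpec",
    "spgr_signal",
    "fit_vfa_r1",
    "fit_vfa_r1_map",
    "m0_for_baseline",
    "si_to_concentration",
    "concentration_to_si",
]

#: Concentration (mM) assigned to frames whose signal reaches or exceeds the
#: SPGR saturation bound M0*sin(alpha), where the inversion is undefined.
SATURATION_CEILING_MM = 50.0


@dataclass(frozen=True)
class AcquisitionParams:
    """Dynamic SPGR acquisition parameters for one resolution.

    Parameters
    ----------
    tr_ms : repetition time in milliseconds.
    te_ms : echo time in milliseconds (informational; TE decay is neglected).
    flip_deg : excitation flip angle in degrees, in (0, 90).
    dt_s : frame interval in seconds.
    n_frames : number of dynamic frames (optional, >= 1).
    """

    tr_ms: float
    te_ms: float
    flip_deg: float
    dt_s: float
    n_frames: int = 1

    def __post_init__(self) -> None:
        if self.tr_ms <= 0:
            raise ValueError(f"TR must be positive, got {self.tr_ms} ms")
        if not 0 < self.flip_deg < 90:
            raise ValueError(f"flip angle must be in (0, 90) deg, got {self.flip_deg}")
        if self.dt_s <= 0:
            raise ValueError(f"frame interval must be positive, got {self.dt_s} s")
        if self.n_frames < 1:
            raise ValueError(f"n_frames must be >= 1, got {self.n_frames}")

    @property
    def tr_s(self) -> float:
        return self.tr_ms * 1e-3

    @property
    def flip_rad(self) -> float:
        return np.deg2rad(self.flip_deg)


@dataclass(frozen=True)
class RelaxationState:
    """Native relaxation state of a voxel: R1_0 (1/s) and M0 (a.u.).

    ``valid`` marks voxels where VFA estimation failed; invalid states carry
    NaN fields and skip the positivity checks so whole-volume mapping never
    aborts.
    """

    r1_0: float
    m0: float
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid:
            if not self.r1_0 > 0:
                raise ValueError(f"R1_0 must be positive, got {self.r1_0}")
            if not self.m0 > 0:
                raise ValueError(f"M0 must be positive, got {self.m0}")

    @classmethod
    def invalid(cls) -> "RelaxationState":
        return cls(r1_0=float("nan"), m0=float("nan"), valid=False)


@dataclass(frozen=True)
class ContrastAgentSpec:
    """Gadolinium-based contrast agent description.

    r1 is the longitudinal relaxivity in 1/(s*mM).  The default 4.2 is a
    literature-typical value for gadoterate at 1.5 T; results that are
    ratio- or round-trip-based do not depend on it.
    """

    r1: float = 4.2
    dose_volume_ml: float = 3.0
    dose_mmol_per_kg: float = 0.020

    def __post_init__(self) -> None:
        if self.r1 <= 0:
            raise ValueError(f"relaxivity must be positive, got {self.r1}")


def spgr_signal(r1, m0, acq: AcquisitionParams):
    """Steady-state spoiled gradient-echo signal.

    S = M0 * sin(a) * (1 - E1) / (1 - cos(a) * E1),  E1 = exp(-TR * R1)

    with TR in seconds.  Accepts scalars or arrays for ``r1``/``m0``.
    """
    r1 = np.asarray(r1, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    if np.any(r1 <= 0):
        raise ValueError("R1 must be positive")
    if np.any(m0 <= 0):
        raise ValueError("M0 must be positive")
    e1 = np.exp(-acq.tr_s * r1)
    a = acq.flip_rad
    out = m0 * np.sin(a) * (1.0 - e1) / (1.0 - np.cos(a) * e1)
    return out if out.ndim else float(out)


def _vfa_linearize(signals: np.ndarray, angles_rad: np.ndarray):
    """Return (x, y) of the DESPOT1 linearization S/tan(a) vs S/sin(a)."""
    y = signals / np.sin(angles_rad)
    x = signals / np.tan(angles_rad)
    return x, y


def fit_vfa_r1(signals, angles_deg, tr_ms: float, refine: bool = True) -> RelaxationState:
    """Estimate (R1_0, M0) from multi-flip-angle SPGR signals.

    Uses the linearized regression of S/sin(a) on S/tan(a) whose slope is
    E1 = exp(-TR*R1_0), optionally followed by one nonlinear refinement pass.
    A slope outside (0, 1) or degenerate signals yield an invalid state
    rather than an exception.
    """
    signals = np.asarray(signals, dtype=float)
    angles_deg = np.asarray(angles_deg, dtype=float)
    if signals.shape != angles_deg.shape or signals.size < 2:
        raise ValueError("need signals for at least two distinct flip angles")
    if np.any(signals < 0):
        raise ValueError("signals must be non-negative")
    if np.unique(angles_deg).size < 2:
        raise ValueError("flip angles must be distinct")

    if not np.any(signals > 0) or np.allclose(signals, signals[0]):
        # flat response across angles carries no R1 information
        return RelaxationState.invalid()

    angles_rad = np.deg2rad(angles_deg)
    x, y = _vfa_linearize(signals, angles_rad)
    xm, ym = x.mean(), y.mean()
    denom = np.sum((x - xm) ** 2)
    if denom == 0:
        return RelaxationState.invalid()
    slope = np.sum((x - xm) * (y - ym)) / denom
    intercept = ym - slope * xm
    if not (0.0 < slope < 1.0) or intercept <= 0:
        return RelaxationState.invalid()

    tr_s = tr_ms * 1e-3
    r1_0 = -np.log(slope) / tr_s
    m0 = intercept / (1.0 - slope)

    if refine:
        from scipy.optimize import least_squares

        def resid(p):
            rr, mm = p
            e1 = np.exp(-tr_s * rr)
            model = mm * np.sin(angles_rad) * (1 - e1) / (1 - np.cos(angles_rad) * e1)
            return model - signals

        sol = least_squares(
            resid, x0=[r1_0, m0], bounds=([1e-6, 1e-6], [np.inf, np.inf]),
            x_scale=[max(r1_0, 1e-3), max(m0, 1e-3)], max_nfev=50,
        )
        if sol.success and np.all(np.isfinite(sol.x)) and np.all(sol.x > 0):
            r1_0, m0 = sol.x

    return RelaxationState(r1_0=float(r1_0), m0=float(m0))


def fit_vfa_r1_map(signals: np.ndarray, angles_deg, tr_ms: float):
    """Vectorized linearized VFA fit over a volume.

    Parameters
    ----------
    signals : array with flip angle on the last axis, shape (..., n_angles).

    Returns
    -------
    (r1_0, m0, valid) arrays of shape ``signals.shape[:-1]``; invalid voxels
    carry NaN.
    """
    signals = np.asarray(signals, dtype=float)
    angles_rad = np.deg2rad(np.asarray(angles_deg, dtype=float))
    with np.errstate(invalid="ignore", divide="ignore"):
        y = signals / np.sin(angles_rad)
        x = signals / np.tan(angles_rad)
        xm = x.mean(axis=-1, keepdims=True)
        ym = y.mean(axis=-1, keepdims=True)
        denom = np.sum((x - xm) ** 2, axis=-1)
        slope = np.where(denom > 0, np.sum((x - xm) * (y - ym), axis=-1) / np.where(denom > 0, denom, 1.0), np.nan)
        intercept = ym[..., 0] - slope * xm[..., 0]
        valid = (slope > 0) & (slope < 1) & (intercept > 0)
        tr_s = tr_ms * 1e-3
        r1_0 = np.where(valid, -np.log(np.where(valid, slope, 0.5)) / tr_s, np.nan)
        m0 = np.where(valid, intercept / (1.0 - np.where(valid, slope, 0.5)), np.nan)
    return r1_0, m0, valid


def m0_for_baseline(baseline_si, r1_0: float, acq: AcquisitionParams):
    """M0 such that the pre-contrast SPGR signal equals ``baseline_si``."""
    unit = spgr_signal(r1_0, 1.0, acq)
    out = np.asarray(baseline_si, dtype=float) / unit
    return out if out.ndim else float(out)


def _invert_spgr(si: np.ndarray, m0, acq: AcquisitionParams):
    """Invert SPGR per frame to R1; returns (r1, saturated_mask)."""
    a = acq.flip_rad
    m0 = np.asarray(m0, dtype=float)
    if m0.ndim and m0.ndim == si.ndim - 1:
        m0 = m0[..., None]  # broadcast per-voxel M0 over the time axis
    smax = m0 * np.sin(a)
    saturated = si >= smax
    # keep the inversion defined where saturated; values are overwritten later
    si_safe = np.where(saturated, 0.5 * smax, si)
    e1 = (smax - si_safe) / (smax - si_safe * np.cos(a))
    e1 = np.clip(e1, 1e-12, 1.0 - 1e-12)
    r1 = -np.log(e1) / acq.tr_s
    return r1, saturated


def si_to_concentration(
    si_series,
    n_baseline: int,
    state: RelaxationState,
    agent: ContrastAgentSpec,
    acq: AcquisitionParams,
    estimate_m0: bool = True,
    ceiling_mm: float = SATURATION_CEILING_MM,
):
    """Convert a dynamic SI series to gadolinium concentration (mM).

    M0 is estimated from the mean of the first ``n_baseline`` frames together
    with R1_0 (set ``estimate_m0=False`` to trust ``state.m0``, e.g. in
    simulations where it is known exactly).  Each frame's SPGR equation is
    inverted to R1(t) and C(t) = (R1(t) - R1_0) / r1.  Baseline frames map to
    approximately zero; negative values from noise are NOT clamped.

    Returns
    -------
    (conc, saturated) : concentration series in mM and a boolean mask of
    frames at/above the saturation bound M0*sin(a), which are set to
    ``ceiling_mm``.
    """
    si = np.asarray(si_series, dtype=float)
    if n_baseline < 1:
        raise ValueError("n_baseline must be >= 1")
    if not state.valid:
        raise ValueError("relaxation state is invalid")
    if estimate_m0:
        m0 = m0_for_baseline(si[..., :n_baseline].mean(axis=-1), state.r1_0, acq)
    else:
        m0 = state.m0
    r1, saturated = _invert_spgr(si, m0, acq)
    conc = (r1 - state.r1_0) / agent.r1
    conc = np.where(saturated, ceiling_mm, conc)
    return conc, saturated


def concentration_to_si(
    conc,
    state: RelaxationState,
    agent: ContrastAgentSpec,
    acq: AcquisitionParams,
):
    """Convert a concentration series (mM) to SPGR signal intensity."""
    if not state.valid:
        raise ValueError("relaxation state is invalid")
    conc = np.asarray(conc, dtype=float)
    r1 = state.r1_0 + agent.r1 * conc
    return spgr_signal(r1, state.m0, acq)
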