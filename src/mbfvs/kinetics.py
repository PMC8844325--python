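"""Irreversible 2-tissue compartment model for ammonia PET, TAC fitting and flow profiles.

Model (rates per minute, activity per mL):

    dC1/dt = K1*Ca - (k2 + k3)*C1
    dC2/dt = k3*C1
    measured(t) = (1 - v_b) * (C1 + C2) + v_b * Ca(t)

with no k4 (irreversible trapping).  Reported MBF is the fitted K1, with no
extraction-fraction correction applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import least_squares
from scipy.signal import lfilter

from .imaging import DynamicSeries, FrameSchedule
from .vessel_roi import TAC, VesselROISet, extract_tac

__all__ = [
    "KineticParams",
    "KineticFit",
    "FlowProfile",
    "DEFAULT_BOUNDS",
    "DEFAULT_INIT",
    "model_tissue_tac",
    "fit_kinetics",
    "vessel_flow_profile",
    "interpolate_profile",
]

# fixed physiological envelope and start point, recorded here for determinism
DEFAULT_BOUNDS: tuple[tuple[float, float], ...] = (
    (0.0, 6.0),  # K1 mL/min/g
    (0.0, 3.0),  # k2 1/min
    (0.0, 3.0),  # k3 1/min
    (0.0, 0.6),  # v_b
)
DEFAULT_INIT: tuple[float, float, float, float] = (0.8, 0.3, 0.1, 0.3)

_FINE_DT_S = 0.1


class KineticsError(ValueError):
    pass


@dataclass(frozen=True)
class KineticParams:
    """2-tissue model parameters; K1 doubles as the MBF estimate (mL/min/g)."""

    K1: float
    k2: float
    k3: float
    v_b: float

    def __post_init__(self) -> None:
        if min(self.K1, self.k2, self.k3, self.v_b) < 0:
            raise KineticsError("kinetic parameters must be non-negative")
        if self.v_b >= 1:
            raise KineticsError("blood fraction v_b must be < 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.K1, self.k2, self.k3, self.v_b])


@dataclass(frozen=True)
class KineticFit:
    params: KineticParams
    residual_norm: float
    converged: bool
    message: str = ""


@dataclass
class FlowProfile:
    """MBF sampled along a vessel, base to apex."""

    vessel: str
    state: str
    positions: np.ndarray  # mm from base
    mbf: np.ndarray  # mL/min/g
    residuals: np.ndarray
    converged: np.ndarray
    provenance: str = "M"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.mbf = np.asarray(self.mbf, dtype=float)
        self.residuals = np.asarray(self.residuals, dtype=float)
        self.converged = np.asarray(self.converged, dtype=bool)
        n = self.positions.size
        if n == 0 or self.mbf.size != n or self.residuals.size != n or self.converged.size != n:
            raise KineticsError("profile arrays must be non-empty and consistent")
        if np.any(np.diff(self.positions) <= 0):
            raise KineticsError("profile positions must be strictly increasing")
        if np.any(self.mbf < 0):
            raise KineticsError("MBF values must be non-negative")

    def __len__(self) -> int:
        return self.positions.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "vessel": self.vessel,
                "state": self.state,
                "provenance": self.provenance,
                "position_mm": self.positions,
                "mbf": self.mbf,
                "residual": self.residuals,
                "converged": self.converged,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------


def _fine_grid(schedule: FrameSchedule, fine_dt: float) -> np.ndarray:
    n = int(np.ceil(schedule.total / fine_dt))
    return np.linspace(0.0, schedule.total, n + 1)


def _sample_input(ca, t_s: np.ndarray) -> np.ndarray:
    """Evaluate an input curve (callable, TAC, or (t, values) pair) on a fine grid."""
    if callable(ca):
        vals = np.asarray(ca(t_s), dtype=float)
    elif isinstance(ca, TAC):
        # frame-mean curve reconstructed by linear interpolation through
        # mid-times, anchored at (0, 0)
        tt = np.concatenate([[0.0], ca.mid_times])
        vv = np.concatenate([[0.0], ca.values])
        vals = np.interp(t_s, tt, vv)
    else:
        tt, vv = ca
        vals = np.interp(t_s, np.asarray(tt, dtype=float), np.asarray(vv, dtype=float))
    if vals.shape != t_s.shape:
        raise KineticsError("input function returned wrong shape")
    return vals


def _expconv(f: np.ndarray, t: np.ndarray, lam: float) -> np.ndarray:
    """Exact ``int_0^t f(s) exp(-lam (t - s)) ds`` for piecewise-linear f on a uniform grid."""
    if lam == 0.0:
        out = np.zeros_like(f)
        out[1:] = np.cumsum((f[1:] + f[:-1]) / 2.0 * np.diff(t))
        return out
    dt = t[1] - t[0]
    e = np.exp(-lam * dt)
    # y[n] = e*y[n-1] + a*f[n-1] + b*f[n], exact for a linear segment
    g = (1.0 - e) / lam
    h = (dt - g) / lam
    a = g - h / dt
    b = h / dt
    y = lfilter([b, a], [1.0, -e], f)
    # lfilter assumes y[0] = b*f[0]; enforce y[0] = 0
    y -= b * f[0] * e ** np.arange(f.size)
    y[0] = 0.0
    return y


def _frame_average(t_s: np.ndarray, y: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    cum = np.concatenate([[0.0], np.cumsum((y[1:] + y[:-1]) / 2.0 * np.diff(t_s))])
    starts = schedule.starts_arr
    ends = schedule.end_times
    f_lo = np.interp(starts, t_s, cum)
    f_hi = np.interp(ends, t_s, cum)
    return (f_hi - f_lo) / schedule.durations_arr


def _model_values(
    theta: np.ndarray, ca_fine: np.ndarray, t_s: np.ndarray, schedule: FrameSchedule
) -> np.ndarray:
    k1, k2, k3, vb = theta
    t_min = t_s / 60.0
    lam = k2 + k3
    i0 = _expconv(ca_fine, t_min, 0.0)
    if lam > 0:
        ilam = _expconv(ca_fine, t_min, lam)
        tissue = k1 * (k3 * i0 + k2 * ilam) / lam
    else:
        tissue = k1 * i0
    measured = (1.0 - vb) * tissue + vb * ca_fine
    return _frame_average(t_s, measured, schedule)


def model_tissue_tac(
    params: KineticParams,
    ca,
    schedule: FrameSchedule,
    fine_dt: float = _FINE_DT_S,
) -> TAC:
    """Frame-duration-averaged model TAC for the given parameters and input curve.

    ``ca`` may be a callable of time (seconds), a blood TAC, or a pre-sampled
    ``(times_s, values)`` pair.
    """
    t_s = _fine_grid(schedule, fine_dt)
    ca_fine = _sample_input(ca, t_s)
    vals = _model_values(params.as_array(), ca_fine, t_s, schedule)
    return TAC(
        mid_times=schedule.mid_times,
        durations=schedule.durations_arr,
        values=vals,
        source="model",
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def fit_kinetics(
    tac: TAC,
    ca,
    weights: np.ndarray | None = None,
    bounds: Sequence[tuple[float, float]] = DEFAULT_BOUNDS,
    init: Sequence[float] = DEFAULT_INIT,
    fit_vb: bool = True,
    fine_dt: float = _FINE_DT_S,
) -> KineticFit:
    """Bounded weighted least-squares fit of the 2-tissue model to a TAC.

    Weights default to the frame durations.  Deterministic given (data, init,
    bounds).  Non-convergence is flagged, never silent: the best-found
    parameters are returned with ``converged=False``.
    """
    starts = tac.mid_times - tac.durations / 2.0
    schedule = FrameSchedule(starts=tuple(starts), durations=tuple(tac.durations))
    t_s = _fine_grid(schedule, fine_dt)
    ca_fine = _sample_input(ca, t_s)
    y = tac.values

    w = tac.durations.copy() if weights is None else np.asarray(weights, dtype=float)
    if w.size != y.size or np.any(w < 0):
        raise KineticsError("weights must be non-negative, one per frame")
    sw = np.sqrt(w / w.sum())

    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    x0 = np.clip(np.asarray(init, dtype=float), lo, hi)

    if not fit_vb:
        vb_fixed = x0[3]

        def resid(x):
            theta = np.array([x[0], x[1], x[2], vb_fixed])
            return sw * (_model_values(theta, ca_fine, t_s, schedule) - y)

        res = least_squares(
            resid, x0[:3], bounds=(lo[:3], hi[:3]), xtol=1e-14, ftol=1e-14, gtol=1e-14
        )
        x = np.array([*res.x, vb_fixed])
    else:

        def resid(x):
            return sw * (_model_values(x, ca_fine, t_s, schedule) - y)

        res = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14)
        x = res.x

    params = KineticParams(K1=float(x[0]), k2=float(x[1]), k3=float(x[2]), v_b=float(x[3]))
    return KineticFit(
        params=params,
        residual_norm=float(np.linalg.norm(res.fun)),
        converged=bool(res.success),
        message=str(res.message),
    )


def vessel_flow_profile(
    roiset: VesselROISet,
    series: DynamicSeries,
    ca,
    state: str | None = None,
    provenance: str = "M",
    **fit_kwargs,
) -> FlowProfile:
    """Fit every ROI TAC independently and assemble the base-to-apex MBF profile.

    A per-ROI fit failure is recorded in the convergence flags; the profile is
    still produced.
    """
    state = series.state if state is None else state
    mbf = np.zeros(len(roiset))
    residuals = np.zeros(len(roiset))
    converged = np.zeros(len(roiset), dtype=bool)
    for i, roi in enumerate(roiset.rois):
        tac = extract_tac(series, roi.voxels, source=f"roi{roi.index}")
        try:
            fit = fit_kinetics(tac, ca, **fit_kwargs)
        except Exception as exc:  # keep going; flag the ROI
            mbf[i] = 0.0
            residuals[i] = np.inf
            converged[i] = False
            continue
        mbf[i] = fit.params.K1
        residuals[i] = fit.residual_norm
        converged[i] = fit.converged
    return FlowProfile(
        vessel=roiset.vessel,
        state=state,
        positions=roiset.positions,
        mbf=mbf,
        residuals=residuals,
        converged=converged,
        provenance=provenance,
    )


def interpolate_profile(profile: FlowProfile, step_mm: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Monotone-preserving piecewise-cubic curve through the ROI flow values."""
    if len(profile) < 2:
        raise KineticsError("interpolation needs at least 2 ROI values")
    interp = PchipInterpolator(profile.positions, profile.mbf)
    s = np.arange(profile.positions[0], profile.positions[-1] + step_mm / 2.0, step_mm)
    s = np.clip(s, profile.positions[0], profile.positions[-1])
    return s, interp(s)
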