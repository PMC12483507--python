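"""Wingbeat kinematics: Fourier fits of wing angles and wingbeat-average summaries.

A tracked wingbeat is three Euler angle time series relative to the stroke
plane (the plane through the wing hinge at 45° to the body long axis):
stroke ``phi`` (fore-aft sweep), deviation ``eta`` (out-of-plane motion) and
rotation ``theta`` (pitch about the spanwise axis).  Each is fitted with a
fourth-order Fourier series over the wingbeat period; the fitted curves give
amplitudes, angular rates, the wingbeat-average angular speed
``omega_bar = 2 f A_phi`` and the mid-stroke angle-of-attack.

Angles are degrees at the interface; the angle-of-attack geometry uses
radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.signal import find_peaks

from .errors import (
    AlignmentError,
    InvalidParameterError,
    UnderdeterminedFitError,
)

__all__ = [
    "WingbeatTrace",
    "FourierFit",
    "WingbeatSummary",
    "BodyKinematicsSummary",
    "fit_wingbeat_fourier",
    "derive_wingbeat_summary",
    "body_kinematics_summary",
    "average_left_right",
    "HOVERING_ADVANCE_RATIO",
    "STROKE_PLANE_OFFSET_DEG",
]

#: Advance ratio below which a wingbeat counts as hovering.
HOVERING_ADVANCE_RATIO = 0.1
#: Stroke plane is fixed at 45 degrees to the body long axis.
STROKE_PLANE_OFFSET_DEG = 45.0

_ANGLES = ("phi", "eta", "theta")


@dataclass
class WingbeatTrace:
    """Time series of the three wing Euler angles (degrees) over >= 1 wingbeat."""

    t: np.ndarray
    phi: np.ndarray
    eta: np.ndarray
    theta: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        if t.ndim != 1 or len(t) < 5:
            raise InvalidParameterError("t must be a 1-D array with >= 5 samples")
        if np.any(np.diff(t) <= 0):
            raise InvalidParameterError("t must be strictly increasing")
        for name in _ANGLES:
            a = np.asarray(getattr(self, name), dtype=float)
            if a.shape != t.shape:
                raise InvalidParameterError(f"{name} must match t in shape")
            if not np.all(np.isfinite(a)):
                raise InvalidParameterError(f"{name} contains non-finite values")
            setattr(self, name, a)
        self.t = t

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.t, "phi_deg": self.phi, "eta_deg": self.eta,
             "theta_deg": self.theta}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "WingbeatTrace":
        return cls(
            t=df["t_s"].to_numpy(), phi=df["phi_deg"].to_numpy(),
            eta=df["eta_deg"].to_numpy(), theta=df["theta_deg"].to_numpy(),
        )


@dataclass
class FourierFit:
    """Fourth-order Fourier series per wing angle over one wingbeat period.

    ``coeffs[angle]`` is ``(a0, a_cos, b_sin)`` with ``a_cos``/``b_sin`` of
    length ``order``; evaluation is periodic by construction.
    """

    period: float
    order: int
    coeffs: dict[str, tuple[float, np.ndarray, np.ndarray]]
    residual_rms: dict[str, float]

    def evaluate(self, angle: str, t: np.ndarray) -> np.ndarray:
        a0, ac, bs = self.coeffs[angle]
        w = 2.0 * np.pi / self.period
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, a0, dtype=float)
        for k in range(1, self.order + 1):
            out += ac[k - 1] * np.cos(k * w * t) + bs[k - 1] * np.sin(k * w * t)
        return out

    def derivative(self, angle: str, t: np.ndarray) -> np.ndarray:
        """Analytic time derivative, in degrees per second."""
        a0, ac, bs = self.coeffs[angle]
        w = 2.0 * np.pi / self.period
        t = np.asarray(t, dtype=float)
        out = np.zeros(t.shape, dtype=float)
        for k in range(1, self.order + 1):
            out += k * w * (-ac[k - 1] * np.sin(k * w * t) + bs[k - 1] * np.cos(k * w * t))
        return out


@dataclass
class WingbeatSummary:
    """Wingbeat-average kinematic parameters derived from a Fourier fit."""

    f: float                 # wingbeat frequency, Hz
    A_phi: float             # stroke amplitude |phi_max - phi_min|, deg
    A_eta: float             # deviation amplitude, deg
    A_theta: float           # rotation amplitude, deg
    omega_bar_deg: float     # 2 f A_phi, deg / s
    omega_bar_rad: float     # same in rad / s
    alpha_bar: float         # mean mid-stroke angle-of-attack, deg
    phi_dot_peak: float      # peak |stroke rate|, deg / s
    eta_dot_peak: float
    theta_dot_peak: float

    def as_dict(self) -> dict[str, float]:
        return {
            "f_Hz": self.f, "Aphi_deg": self.A_phi, "Aeta_deg": self.A_eta,
            "Atheta_deg": self.A_theta, "omega_deg_s": self.omega_bar_deg,
            "omega_rad_s": self.omega_bar_rad, "alpha_deg": self.alpha_bar,
            "phidot_peak_deg_s": self.phi_dot_peak,
            "etadot_peak_deg_s": self.eta_dot_peak,
            "thetadot_peak_deg_s": self.theta_dot_peak,
        }


@dataclass
class BodyKinematicsSummary:
    """Whole-sequence body kinematics and the hovering classification."""

    U: float                  # mean flight speed, m / s
    gamma_climb: float        # climb angle, deg
    beta_body: float          # body pitch, deg
    beta_strokeplane: float   # beta_body - 45, deg
    J: float                  # advance ratio U / (omega_bar R)
    f_hat: float              # sequence-mean wingbeat frequency, Hz
    hovering: bool            # J < 0.1

    def as_dict(self) -> dict[str, float]:
        return {
            "U_m_s": self.U, "gamma_climb_deg": self.gamma_climb,
            "beta_body_deg": self.beta_body,
            "beta_strokeplane_deg": self.beta_strokeplane,
            "J": self.J, "f_hat_Hz": self.f_hat, "hovering": bool(self.hovering),
        }


def _design_matrix(t: np.ndarray, period: float, order: int) -> np.ndarray:
    w = 2.0 * np.pi / period
    cols = [np.ones_like(t)]
    for k in range(1, order + 1):
        cols.append(np.cos(k * w * t))
        cols.append(np.sin(k * w * t))
    return np.column_stack(cols)


def _initial_period(t: np.ndarray, phi: np.ndarray) -> float:
    """First guess of the wingbeat period: spacing of successive stroke maxima,
    falling back to the dominant FFT frequency for short traces."""
    x = phi - phi.mean()
    span = x.max() - x.min()
    if span > 0:
        peaks, _ = find_peaks(x, prominence=0.3 * span)
        if len(peaks) >= 2:
            return float(np.mean(np.diff(t[peaks])))
    dt = float(np.median(np.diff(t)))
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(len(x), dt)
    k = int(np.argmax(spec[1:])) + 1
    if freqs[k] <= 0:
        raise InvalidParameterError("could not identify a wingbeat period")
    return float(1.0 / freqs[k])


def fit_wingbeat_fourier(trace: WingbeatTrace, order: int = 4) -> FourierFit:
    """Least-squares Fourier fit of all three wing angles with a shared period.

    The period is first bracketed from successive stroke-angle maxima (FFT
    fallback for traces with fewer than two maxima) and then refined by
    minimising the stroke-angle residual sum of squares over the period
    (variable projection), consistent with stroke-maxima wingbeat
    segmentation; noiseless sinusoidal strokes are recovered to solver
    tolerance.  If the stroke angle is constant the deviation or rotation
    angle is used for the period instead.
    """
    n_coef = 2 * order + 1
    t = trace.t - trace.t[0]
    if len(t) < n_coef:
        raise UnderdeterminedFitError(
            f"{len(t)} samples cannot determine {n_coef} Fourier coefficients"
        )
    Y = np.column_stack([trace.phi, trace.eta, trace.theta])

    ref = next(
        (sig for sig in (trace.phi, trace.eta, trace.theta) if np.ptp(sig) > 0),
        None,
    )
    if ref is None:
        # all angles constant: no period information; fit means only
        period = float(t[-1] - t[0])
    else:
        p0 = _initial_period(t, ref)

        def ssr(period: float) -> float:
            A = _design_matrix(t, period, order)
            beta, _, _, _ = np.linalg.lstsq(A, ref, rcond=None)
            resid = ref - A @ beta
            return float(resid @ resid)

        opt = minimize_scalar(
            ssr, bounds=(0.75 * p0, 1.35 * p0), method="bounded",
            options={"xatol": p0 * 1e-12},
        )
        period = float(opt.x)

    A = _design_matrix(t, period, order)
    beta, _, _, _ = np.linalg.lstsq(A, Y, rcond=None)
    resid = Y - A @ beta
    coeffs = {}
    rms = {}
    for j, name in enumerate(_ANGLES):
        b = beta[:, j]
        coeffs[name] = (float(b[0]), b[1::2].copy(), b[2::2].copy())
        rms[name] = float(np.sqrt(np.mean(resid[:, j] ** 2)))
    return FourierFit(period=period, order=order, coeffs=coeffs, residual_rms=rms)


def angle_of_attack(
    phi_dot: np.ndarray, eta_dot: np.ndarray, theta_deg: np.ndarray
) -> np.ndarray:
    """Geometric angle-of-attack (degrees) of a rigid flat wing.

    The wing velocity direction lies in the plane spanned by the stroke
    tangent (rate ``phi_dot``) and the stroke-plane normal (rate
    ``eta_dot``); the wing surface is pitched by ``theta`` about the spanwise
    axis, with ``theta = 0`` meaning the chord is perpendicular to the stroke
    plane.  Then ``sin(alpha) = |phi_dot cos(theta) - eta_dot sin(theta)| /
    sqrt(phi_dot^2 + eta_dot^2)``; for pure stroke motion this reduces to
    ``alpha = 90° - |theta|``.  Undefined (NaN) where the wing is at rest
    (stroke reversal with zero deviation rate).
    """
    th = np.deg2rad(theta_deg)
    speed = np.hypot(phi_dot, eta_dot)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.abs(phi_dot * np.cos(th) - eta_dot * np.sin(th)) / speed
    alpha = np.rad2deg(np.arcsin(np.clip(s, 0.0, 1.0)))
    alpha[speed <= 0] = np.nan
    return alpha


def derive_wingbeat_summary(
    fit: FourierFit, station_fraction: float = 1.0
) -> WingbeatSummary:
    """Wingbeat-average parameters from a Fourier fit.

    Amplitudes are peak-to-peak extrema of the fitted curves over one period;
    ``omega_bar = 2 f A_phi`` by definition.  The mean angle-of-attack is the
    average of the angle-of-attack at the two mid-stroke phases (the extrema
    of the stroke rate), where force production peaks.  ``station_fraction``
    selects the spanwise reference station of the flapping velocity; for a
    rigid flat wing the angle-of-attack is independent of it, so it only
    matters for downstream velocity magnitudes.
    """
    if not 0 < station_fraction <= 1:
        raise InvalidParameterError("station_fraction must be in (0, 1]")
    f = 1.0 / fit.period
    tau = np.linspace(0.0, fit.period, 2001)
    phi = fit.evaluate("phi", tau)
    eta = fit.evaluate("eta", tau)
    theta = fit.evaluate("theta", tau)
    phid = fit.derivative("phi", tau)
    etad = fit.derivative("eta", tau)
    thetad = fit.derivative("theta", tau)

    A_phi = float(np.ptp(phi))
    A_eta = float(np.ptp(eta))
    A_theta = float(np.ptp(theta))
    omega_deg = 2.0 * f * A_phi
    omega_rad = np.deg2rad(omega_deg)

    alpha = angle_of_attack(phid, etad, theta)
    mid = [int(np.argmax(phid)), int(np.argmin(phid))]
    alpha_mid = alpha[mid]
    alpha_bar = float(np.nanmean(alpha_mid)) if np.any(np.isfinite(alpha_mid)) else float("nan")

    return WingbeatSummary(
        f=f, A_phi=A_phi, A_eta=A_eta, A_theta=A_theta,
        omega_bar_deg=omega_deg, omega_bar_rad=float(omega_rad),
        alpha_bar=alpha_bar,
        phi_dot_peak=float(np.max(np.abs(phid))),
        eta_dot_peak=float(np.max(np.abs(etad))),
        theta_dot_peak=float(np.max(np.abs(thetad))),
    )


def body_kinematics_summary(
    body: pd.DataFrame,
    n_wingbeats: float,
    omega_bar_rad: float,
    R_m: float,
    sequence_duration: float | None = None,
) -> BodyKinematicsSummary:
    """Body kinematics over a flight sequence and the hovering classification.

    ``body`` needs columns ``t_s, x_m, y_m, z_m, body_pitch_deg`` (z vertical).
    Velocity uses a central temporal differentiation scheme; the advance ratio
    ``J = U / (omega_bar R)`` compares flight speed to the wingtip speed, and
    ``J < 0.1`` flags hovering.
    """
    if len(body) < 3:
        raise InvalidParameterError("need >= 3 body positions")
    if R_m <= 0 or omega_bar_rad < 0:
        raise InvalidParameterError("R_m must be > 0 and omega_bar_rad >= 0")
    t = body["t_s"].to_numpy(dtype=float)
    vx = np.gradient(body["x_m"].to_numpy(dtype=float), t)
    vy = np.gradient(body["y_m"].to_numpy(dtype=float), t)
    vz = np.gradient(body["z_m"].to_numpy(dtype=float), t)
    U_hor = float(np.hypot(vx.mean(), vy.mean()))
    U_ver = float(vz.mean())
    U = float(np.sqrt(U_hor**2 + U_ver**2))
    gamma = float(np.degrees(np.arctan2(U_ver, U_hor)))
    beta_body = float(np.mean(body["body_pitch_deg"].to_numpy(dtype=float)))
    beta_sp = beta_body - STROKE_PLANE_OFFSET_DEG
    J = 0.0 if U == 0 else (float("inf") if omega_bar_rad == 0 else U / (omega_bar_rad * R_m))
    T = sequence_duration if sequence_duration is not None else float(t[-1] - t[0])
    if T <= 0:
        raise InvalidParameterError("sequence duration must be > 0")
    return BodyKinematicsSummary(
        U=U, gamma_climb=gamma, beta_body=beta_body, beta_strokeplane=beta_sp,
        J=J, f_hat=n_wingbeats / T, hovering=bool(J < HOVERING_ADVANCE_RATIO),
    )


def average_left_right(trace_L: WingbeatTrace, trace_R: WingbeatTrace) -> WingbeatTrace:
    """Pointwise mean of left and right wing angles on a shared timebase."""
    if len(trace_L.t) != len(trace_R.t):
        raise AlignmentError("left/right traces differ in length")
    dt = float(np.median(np.diff(trace_L.t)))
    if np.max(np.abs(trace_L.t - trace_R.t)) > dt:
        raise AlignmentError("left/right timebases differ by more than one sample")
    return WingbeatTrace(
        t=trace_L.t.copy(),
        phi=0.5 * (trace_L.phi + trace_R.phi),
        eta=0.5 * (trace_L.eta + trace_R.eta),
        theta=0.5 * (trace_L.theta + trace_R.theta),
    )
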