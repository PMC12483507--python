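"""Quasi-steady hovering force model, scaling baselines, and the relative
allometric scaling factor.

Model
-----
The wingbeat-average vertical force of one beating wing in hover is

.. math:: \\bar F = \\tfrac12 \\rho S_2 \\bar\\omega^2 \\bar C_F,
          \\qquad \\bar C_F = \\sin(\\bar\\alpha)\\, \\bar C_{F\\alpha},

with air density ``rho``, second-moment-of-area ``S2``, wingbeat-average
angular speed ``omega_bar = 2 f A_phi`` and the angle-of-attack-specific
force coefficient ``C_F_alpha``.  Substituting ``S2 = R^3 c̄ S2*`` and
``omega_bar = 2 f A_phi`` decomposes the force into separate morphology
(``R``, ``c̄``, ``S2*``) and kinematics (``f``, ``A_phi``, ``alpha``)
factors; both factorisations are algebraically identical and the code
asserts as much.

Scaling baselines
-----------------
Under geometric similarity all lengths scale as ``m^(1/3)`` so
``F ~ S2 ~ m^(4/3)``; under kinematic similarity the dimensionless and rate
kinematic parameters are mass-invariant.  Requiring ``F ~ m`` (weight
support) through allometry of a *single* metric, everything else at
similarity, gives that metric's weight-support exponent ``a_ws`` (e.g.
``R ~ m^(2/9)``, ``f ~ m^(-1/6)``).  The relative allometric scaling factor

.. math:: a^* = 100\\,\\frac{a_{allo} - a_{sim}}{a_{ws} - a_{sim}}\\,[\\%]

expresses what fraction of the compensation needed for weight support a
metric's observed allometry provides (0% = similarity, 100% = full
single-metric compensation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "AeroParams",
    "ScalingBaseline",
    "ContributionResult",
    "quasi_steady_force",
    "quasi_steady_force_decomposed",
    "weight_support_ratio",
    "frequency_rescale",
    "expected_exponents",
    "relative_scaling_factor",
    "contribution_decomposition",
    "calibrate_force_coefficient",
    "round_half_away",
    "BASELINE_EXPONENTS",
    "COMPONENT_METRICS",
]

MG_TO_KG = 1e-6


@dataclass(frozen=True)
class AeroParams:
    """Physical constants of the quasi-steady force model (SI)."""

    rho: float = 1.225          # air density, kg m^-3
    g: float = 9.81             # gravitational acceleration, m s^-2
    C_F_alpha: float = 1.8      # angle-of-attack-specific force coefficient
    n_wings: int = 2            # wings contributing to weight support

    def __post_init__(self):
        if self.rho <= 0 or self.C_F_alpha <= 0 or self.g <= 0:
            raise InvalidParameterError("rho, g, and C_F_alpha must be > 0")
        if self.n_wings < 1:
            raise InvalidParameterError("n_wings must be >= 1")


@dataclass(frozen=True)
class ScalingBaseline:
    """Similarity and single-metric weight-support exponents for one metric."""

    metric: str
    a_sim: float
    a_ws: float


#: (a_sim, a_ws) per metric, derived from F ~ S2 omega^2, S2 = R^3 c S2*,
#: omega ~ f A_phi, C_F ~ sin(alpha), all other metrics held at similarity.
BASELINE_EXPONENTS: dict[str, tuple[float, float]] = {
    "S2": (4.0 / 3.0, 1.0),
    "R": (1.0 / 3.0, 2.0 / 9.0),
    "c_bar": (1.0 / 3.0, 0.0),
    "S2_star": (0.0, -1.0 / 3.0),
    "f": (0.0, -1.0 / 6.0),
    "A_phi": (0.0, -1.0 / 6.0),
    "omega_bar": (0.0, -1.0 / 6.0),
    "alpha": (0.0, -1.0 / 3.0),
    "S2_omega2": (4.0 / 3.0, 1.0),
}

#: Metrics whose a* values decompose the force model's weight-support budget.
COMPONENT_METRICS = ("f", "R", "c_bar", "S2_star")


def quasi_steady_force(
    S2: float, omega_bar: float, alpha_bar: float, params: AeroParams = AeroParams()
) -> tuple[float, float]:
    """Wingbeat-average vertical force (N): ``(per wing, total)``.

    Inputs are SI: ``S2`` in m^4, ``omega_bar`` in rad/s, ``alpha_bar`` in rad.
    """
    if S2 < 0 or omega_bar < 0:
        raise InvalidParameterError("S2 and omega_bar must be >= 0")
    if not 0 < alpha_bar < math.pi:
        raise InvalidParameterError("alpha_bar must be in (0, pi)")
    F = 0.5 * params.rho * S2 * omega_bar**2 * math.sin(alpha_bar) * params.C_F_alpha
    return F, params.n_wings * F


def quasi_steady_force_decomposed(
    R: float,
    c_bar: float,
    S2_star: float,
    f: float,
    A_phi: float,
    alpha_bar: float,
    params: AeroParams = AeroParams(),
) -> tuple[float, float]:
    """Decomposed force path: morphology (R, c̄, S2*) times kinematics (f, A_phi).

    SI units: m, Hz, rad.  Uses ``omega_bar = 2 f A_phi``, so it agrees with
    :func:`quasi_steady_force` on ``S2 = R^3 c̄ S2*`` to machine precision.
    """
    if min(R, c_bar, S2_star, f, A_phi) < 0:
        raise InvalidParameterError("morphology and kinematics inputs must be >= 0")
    if not 0 < alpha_bar < math.pi:
        raise InvalidParameterError("alpha_bar must be in (0, pi)")
    F = (
        0.5 * params.rho * (R**3 * c_bar * S2_star) * (2.0 * f * A_phi) ** 2
        * math.sin(alpha_bar) * params.C_F_alpha
    )
    return F, params.n_wings * F


def weight_support_ratio(
    F_total: float, mass_mg: float, params: AeroParams = AeroParams()
) -> float:
    """Total vertical force divided by body weight; 1 means hovering equilibrium."""
    if mass_mg <= 0:
        raise InvalidParameterError("mass must be > 0")
    return F_total / (mass_mg * MG_TO_KG * params.g)


def frequency_rescale(F: float, f: float, f_mean: float) -> float:
    """Rescale a force computed at ``f_mean`` to frequency ``f``: ``F (f/f_mean)^2``."""
    if f <= 0 or f_mean <= 0:
        raise InvalidParameterError("frequencies must be > 0")
    return F * (f / f_mean) ** 2


def expected_exponents(metric: str) -> ScalingBaseline:
    """Similarity and single-metric weight-support exponents for ``metric``."""
    try:
        a_sim, a_ws = BASELINE_EXPONENTS[metric]
    except KeyError:
        raise InvalidParameterError(
            f"unknown metric {metric!r}; expected one of {sorted(BASELINE_EXPONENTS)}"
        ) from None
    return ScalingBaseline(metric=metric, a_sim=a_sim, a_ws=a_ws)


def relative_scaling_factor(a_allo: float, a_sim: float, a_ws: float) -> float:
    """Relative allometric scaling factor ``a*`` in percent."""
    if a_ws == a_sim:
        raise InvalidParameterError(
            "weight-support and similarity exponents coincide; a* undefined"
        )
    return 100.0 * (a_allo - a_sim) / (a_ws - a_sim)


def round_half_away(x: float) -> int:
    """Round half away from zero (matches conventional table rounding).

    The value is first rounded to 9 decimals so exact halves that float
    arithmetic lands epsilon below (e.g. 70.499999999999986 for 70.5) are
    still treated as halves.
    """
    x = round(x, 9)
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


@dataclass
class MetricContribution:
    metric: str
    a_allo: float
    a_sim: float
    a_ws: float
    a_star: float            # percent, unrounded
    a_star_rounded: int      # percent, half away from zero
    significant: bool | None = None


@dataclass
class ContributionResult:
    """Per-metric a* values plus the component sum of the force decomposition."""

    per_metric: dict[str, MetricContribution]
    components: tuple[str, ...]
    component_sum: float          # sum of unrounded component a*
    component_sum_rounded: int    # sum of rounded component a*

    def as_records(self) -> list[dict]:
        return [
            {
                "metric": m.metric, "a_allo": m.a_allo, "a_sim": m.a_sim,
                "a_ws": m.a_ws, "a_star_percent": m.a_star,
                "a_star_rounded": m.a_star_rounded,
                "significant": m.significant,
                "is_component": m.metric in self.components,
            }
            for m in self.per_metric.values()
        ]


def contribution_decomposition(fits: dict[str, object]) -> ContributionResult:
    """a* per metric and the decomposition component sum.

    ``fits`` maps metric names (keys of :data:`BASELINE_EXPONENTS`) to either
    a bare allometric slope or any object with ``slope`` and ``p`` attributes
    (e.g. a fitted ``ScalingFit``).  The component sum is taken over
    ``{f, R, c_bar, S2_star}`` when all four are present (the full
    decomposition of the force model), otherwise over ``{S2, f}``.
    """
    per: dict[str, MetricContribution] = {}
    for metric, fit in fits.items():
        base = expected_exponents(metric)
        slope = getattr(fit, "slope", fit)
        p = getattr(fit, "p", None)
        a_star = relative_scaling_factor(float(slope), base.a_sim, base.a_ws)
        per[metric] = MetricContribution(
            metric=metric, a_allo=float(slope), a_sim=base.a_sim, a_ws=base.a_ws,
            a_star=a_star, a_star_rounded=round_half_away(a_star),
            significant=(None if p is None else bool(p < 0.05)),
        )
    if all(m in per for m in COMPONENT_METRICS):
        components = COMPONENT_METRICS
    elif "S2" in per and "f" in per:
        components = ("S2", "f")
    else:
        raise InvalidParameterError(
            "decomposition needs metrics {f, R, c_bar, S2_star} or {S2, f}"
        )
    total = sum(per[m].a_star for m in components)
    total_rounded = sum(per[m].a_star_rounded for m in components)
    return ContributionResult(
        per_metric=per, components=components,
        component_sum=total, component_sum_rounded=total_rounded,
    )


def calibrate_force_coefficient(
    S2: np.ndarray,
    omega_bar: np.ndarray,
    alpha_bar: np.ndarray,
    mass_mg: np.ndarray,
    params: AeroParams = AeroParams(),
) -> AeroParams:
    """Set ``C_F_alpha`` so the mass-weighted mean weight-support ratio is 1.

    The force is linear in ``C_F_alpha``, so the calibration is a single
    division.  Inputs are SI arrays (m^4, rad/s, rad) plus masses in mg.
    """
    S2 = np.asarray(S2, float)
    omega_bar = np.asarray(omega_bar, float)
    alpha_bar = np.asarray(alpha_bar, float)
    mass_mg = np.asarray(mass_mg, float)
    if np.any(mass_mg <= 0):
        raise InvalidParameterError("masses must be > 0")
    unit = replace(params, C_F_alpha=1.0)
    ratios = np.array(
        [
            weight_support_ratio(
                quasi_steady_force(s2, w, a, unit)[1], m, unit
            )
            for s2, w, a, m in zip(S2, omega_bar, alpha_bar, mass_mg)
        ]
    )
    weights = mass_mg / mass_mg.sum()
    mean_ratio = float(weights @ ratios)
    if mean_ratio <= 0:
        raise InvalidParameterError("cannot calibrate: non-positive mean ratio")
    return replace(params, C_F_alpha=1.0 / mean_ratio)
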