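"""Synthetic hoverfly-like data with known scaling structure.

Every downstream stage of the package (morphometrics, kinematics,
aerodynamics, phylogenetic regression) is exercised on data from this
module: a pure-birth phylogeny with log10 body mass evolving under Brownian
motion, parametric wing outlines whose chord profile is a scaled Beta(p, q)
density (so the normalised second-moment-of-area is known in closed form:
the Beta distribution's second raw moment ``p(p+1)/((p+q)(p+q+1))``), and
periodic wingbeat traces with configurable additive angle noise.

Three scaling scenarios define how species traits co-vary with body mass
``m`` (exponents on the log10 scale, exact at zero noise):

``isometry``
    geometric + kinematic similarity: ``R, c̄ ~ m^(1/3)``, ``S2*`` and all
    kinematics mass-invariant — so ``S2 ~ m^(4/3)`` and hovering force
    under-supports weight in small species;
``morphology_compensated``
    wing morphology alone restores weight support: ``R ~ m^(2/9)`` (chord
    isometric, shape constant) so ``S2 ~ m``;
``kinematics_compensated``
    morphology isometric, wingbeat frequency ``f ~ m^(-1/6)`` restores
    weight support through the kinematics.

Residual biological scatter is log-normal on each trait (multiplicative,
SD ``noise_sd_log10`` in log10 units); angle noise is Gaussian in degrees.
All randomness flows from the config seed through named substreams, so a
given config is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.optimize import brentq

from .errors import InvalidParameterError, OutlineGenerationError, UndersamplingError
from .kinematics import WingbeatTrace
from .trees import simulate_bm_trait, simulate_yule_tree
from .wingmorph import WingOutline

__all__ = [
    "ScenarioConfig",
    "SCENARIOS",
    "simulate_clade",
    "synth_wing_outline",
    "synth_wingbeat_trace",
    "generate_species_set",
    "beta_shape_for_s2star",
    "beta_s2star",
    "scenario_exponents",
    "write_species_set",
]

SCENARIOS = ("isometry", "morphology_compensated", "kinematics_compensated")

# Reference trait values at the reference mass (geometric mid of the mass
# range): a mid-sized hoverfly with span ~8 mm, chord ~2.7 mm, f ~186 Hz,
# stroke amplitude 100 deg, mid-stroke angle-of-attack 42 deg.
REFERENCE_TRAITS = {
    "R_mm": 8.0,
    "cbar_mm": 2.7,
    "S2star": 0.37,
    "f_Hz": 186.0,
    "Aphi_deg": 100.0,
    "alpha_deg": 42.0,
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Generative settings for a species set under one scaling scenario."""

    n_species: int = 28
    mass_range: tuple[float, float] = (3.0, 132.0)   # mg
    scenario: str = "isometry"
    shape_exponent: float = 0.0       # S2* vs mass exponent override
    noise_sd_log10: float = 0.02      # residual SD of log10 traits
    kin_noise_sd: float = 2.0         # angle noise, degrees
    seed: int = 0
    birth_rate: float = 1.0
    sigma2_bm: float = 1.0            # BM rate of log10 mass (unit-depth tree)

    def __post_init__(self):
        lo, hi = self.mass_range
        if not (lo > 0 and lo < hi):
            raise InvalidParameterError("mass_range must satisfy 0 < min < max")
        if self.n_species < 3:
            raise InvalidParameterError("n_species must be >= 3")
        if self.noise_sd_log10 < 0 or self.kin_noise_sd < 0:
            raise InvalidParameterError("noise SDs must be >= 0")
        if self.scenario not in SCENARIOS:
            raise InvalidParameterError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )
        if self.birth_rate <= 0 or self.sigma2_bm < 0:
            raise InvalidParameterError("birth_rate > 0 and sigma2_bm >= 0 required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise InvalidParameterError("config must set a seed")
        if "mass_range" in raw:
            raw["mass_range"] = tuple(raw["mass_range"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mass_range"] = list(d["mass_range"])
        return d


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named, order-independent child RNG derived from one base seed."""
    h = int.from_bytes(name.encode(), "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(h,)))


def simulate_clade(
    n_species: int,
    birth_rate: float = 1.0,
    sigma2_bm: float = 1.0,
    root_mass_log10: float = np.log10(20.0),
    seed: int = 0,
) -> tuple[dendropy.Tree, dict[str, float]]:
    """A pure-birth clade (unit depth) with BM-evolved body masses (mg).

    Returns the tree and a tip -> mass map; identical seed and arguments
    reproduce the identical Newick string and masses.
    """
    if n_species < 3:
        raise InvalidParameterError("n_species must be >= 3")
    if birth_rate <= 0 or sigma2_bm < 0:
        raise InvalidParameterError("birth_rate > 0 and sigma2_bm >= 0 required")
    tree = simulate_yule_tree(n_species, birth_rate, _substream(seed, "tree"))
    logm = simulate_bm_trait(tree, sigma2_bm, root_mass_log10, _substream(seed, "mass"))
    return tree, {sp: 10.0**v for sp, v in logm.items()}


def beta_s2star(p: float, q: float) -> float:
    """Closed-form S2* of a Beta(p, q) chord profile (second raw moment)."""
    return p * (p + 1.0) / ((p + q) * (p + q + 1.0))


def beta_shape_for_s2star(s2star: float, q: float = 2.5) -> tuple[float, float]:
    """Solve for p so a Beta(p, q) chord profile has the requested S2*."""
    lo, hi = 1.0, 500.0
    if not beta_s2star(lo, q) < s2star < beta_s2star(hi, q):
        raise InvalidParameterError(
            f"S2*={s2star:.3f} out of reach for Beta(p, {q}) with p in [1, 500]"
        )
    p = brentq(lambda pp: beta_s2star(pp, q) - s2star, lo, hi, xtol=1e-12)
    return float(p), q


def synth_wing_outline(
    R: float,
    c_bar: float,
    beta_p: float,
    beta_q: float,
    n_points: int = 300,
    specimen_id: str = "",
) -> WingOutline:
    """Wing outline with chord profile proportional to the Beta(p, q) density.

    The outline is the upper/lower boundary ``y = ±c(r)/2`` around the span
    axis, closed at hinge (origin) and tip ``(R, 0)``; the enclosed area is
    normalised to ``R * c_bar`` exactly, which leaves S2* untouched (chord
    rescaling cancels in ``S2 / (R^3 c̄)``).
    """
    if R <= 0 or c_bar <= 0:
        raise InvalidParameterError("R and c_bar must be > 0")
    if beta_p <= 0 or beta_q <= 0:
        raise InvalidParameterError("beta_p and beta_q must be > 0")
    if n_points < 50:
        raise InvalidParameterError("n_points must be >= 50")
    if beta_p < 1 or beta_q < 1:
        raise OutlineGenerationError(
            "Beta shape parameters < 1 give an unbounded chord at hinge or tip"
        )
    n_half = max(n_points // 2, 25)
    t = np.linspace(0.0, 1.0, n_half)
    c = c_bar * stats.beta.pdf(t, beta_p, beta_q)
    # normalise enclosed (trapezoid) area to R * c_bar exactly
    area = np.trapezoid(c, t * R)
    if area <= 0:
        raise OutlineGenerationError("degenerate chord profile")
    c *= (R * c_bar) / area
    x = t * R
    upper = np.column_stack([x, +0.5 * c])
    lower = np.column_stack([x, -0.5 * c])[::-1]
    pts = np.vstack([[[0.0, 0.0]], upper, [[R, 0.0]], lower])
    # drop consecutive duplicates (degenerate hinge/tip edges when c -> 0)
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(np.abs(np.diff(pts, axis=0)) > 1e-12 * max(R, c_bar), axis=1)
    if np.allclose(pts[0], pts[-1]):
        keep[-1] = False
    pts = pts[keep]
    try:
        return WingOutline(points=pts, hinge_index=0, specimen_id=specimen_id)
    except Exception as exc:
        raise OutlineGenerationError(f"invalid outline: {exc}") from exc


def synth_wingbeat_trace(
    f: float,
    A_phi: float,
    A_eta: float = 10.0,
    A_theta: float | None = None,
    alpha_mid: float = 42.0,
    n_wingbeats: int = 3,
    sample_rate: float | None = None,
    kin_noise_sd: float = 0.0,
    seed: int = 0,
) -> WingbeatTrace:
    """Template wingbeat trace: sinusoidal stroke, second-harmonic deviation,
    plateau-flattened square-wave-like rotation.

    The stroke angle is a pure fundamental with peak-to-peak amplitude
    ``A_phi``; deviation is a small fundamental + second-harmonic pattern;
    the rotation angle is the third-harmonic-flattened square wave
    ``theta_m (9/8 sin + 1/8 sin3)`` whose mid-stroke plateau sets the
    angle-of-attack.  All templates are band-limited to harmonic order <= 3,
    so a fourth-order Fourier fit reproduces them (and hence f, A_phi and
    alpha_mid) exactly at zero noise.  If ``A_theta`` is omitted it is
    derived as ``2 (90° - alpha_mid)`` so the configured ``alpha_mid`` is
    realised; an explicit ``A_theta`` takes precedence.
    """
    if f <= 0:
        raise InvalidParameterError("f must be > 0")
    if A_phi < 0 or A_eta < 0 or (A_theta is not None and A_theta < 0):
        raise InvalidParameterError("amplitudes must be >= 0")
    if not 0 < alpha_mid <= 90:
        raise InvalidParameterError("alpha_mid must be in (0, 90] degrees")
    if sample_rate is None:
        sample_rate = 40.0 * f
    if sample_rate < 20.0 * f:
        raise UndersamplingError(
            f"sample_rate {sample_rate:g} Hz < 20 x wingbeat frequency {f:g} Hz"
        )
    n = int(round(n_wingbeats * sample_rate / f))
    t = np.arange(n) / sample_rate
    w = 2.0 * np.pi * f
    phi = 0.5 * A_phi * np.cos(w * t)
    eta = 0.5 * A_eta * (0.15 * np.sin(w * t) + 0.85 * np.cos(2.0 * w * t))
    theta_amp = 0.5 * A_theta if A_theta is not None else (90.0 - alpha_mid)
    # mid-stroke (wt = pi/2) value is exactly theta_amp: 9/8 - 1/8 = 1
    theta = theta_amp * (1.125 * np.sin(w * t) + 0.125 * np.sin(3.0 * w * t))
    if kin_noise_sd > 0:
        rng = _substream(seed, "trace")
        phi = phi + rng.normal(0.0, kin_noise_sd, n)
        eta = eta + rng.normal(0.0, kin_noise_sd, n)
        theta = theta + rng.normal(0.0, kin_noise_sd, n)
    return WingbeatTrace(t=t, phi=phi, eta=eta, theta=theta)


def scenario_exponents(config: ScenarioConfig) -> dict[str, float]:
    """Generative log-log mass exponent of every trait under the scenario."""
    s = config.shape_exponent
    if config.scenario == "isometry":
        a_R = 1.0 / 3.0
    elif config.scenario == "morphology_compensated":
        # choose the wingspan exponent so S2 = S2* R^3 c_bar scales as m
        a_R = (2.0 / 3.0 - s) / 3.0
    else:
        a_R = 1.0 / 3.0
    a_f = -1.0 / 6.0 if config.scenario == "kinematics_compensated" else 0.0
    return {
        "R_mm": a_R,
        "cbar_mm": 1.0 / 3.0,
        "S2star": s,
        "f_Hz": a_f,
        "Aphi_deg": 0.0,
        "alpha_deg": 0.0,
    }


def generate_species_set(config: ScenarioConfig) -> tuple[dendropy.Tree, pd.DataFrame]:
    """Phylogeny plus per-species trait table under the configured scenario.

    Body masses are BM tip values affinely mapped (log10 scale) onto
    ``mass_range``, preserving the phylogenetic correlation structure while
    guaranteeing every mass lies inside the range.  Trait means follow the
    scenario's power laws of mass with log-normal residual noise.
    """
    tree, mass = simulate_clade(
        config.n_species,
        birth_rate=config.birth_rate,
        sigma2_bm=config.sigma2_bm,
        root_mass_log10=0.0,
        seed=config.seed,
    )
    species = sorted(mass)
    logm = np.log10(np.array([mass[sp] for sp in species]))
    lo, hi = np.log10(config.mass_range[0]), np.log10(config.mass_range[1])
    if np.ptp(logm) > 0:
        logm = lo + (logm - logm.min()) * (hi - lo) / np.ptp(logm)
    else:
        logm = np.full_like(logm, 0.5 * (lo + hi))
    m = 10.0**logm
    m_ref = float(np.sqrt(config.mass_range[0] * config.mass_range[1]))
    expo = scenario_exponents(config)
    rng = _substream(config.seed, "traits")
    df = pd.DataFrame({"species": species, "mass_mg": m}).set_index("species")
    for trait, a in expo.items():
        base = REFERENCE_TRAITS[trait] * (m / m_ref) ** a
        if config.noise_sd_log10 > 0:
            base = base * 10.0 ** rng.normal(0.0, config.noise_sd_log10, len(m))
        df[trait] = base
    df["S2_mm4"] = df["S2star"] * df["R_mm"] ** 3 * df["cbar_mm"]
    return tree, df.reset_index()


def write_species_set(
    tree: dendropy.Tree,
    traits: pd.DataFrame,
    outdir: str | Path,
    config: ScenarioConfig | None = None,
    float_format: str = "%.6g",
) -> dict[str, Path]:
    """Write the Newick tree, trait table CSV, and a config echo JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": outdir / "tree.nwk",
        "traits": outdir / "species_traits.csv",
    }
    paths["tree"].write_text(tree.as_string(schema="newick"))
    traits.to_csv(paths["traits"], index=False, float_format=float_format)
    if config is not None:
        paths["config"] = outdir / "config_echo.json"
        paths["config"].write_text(json.dumps(config.to_dict(), indent=2))
    return paths
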