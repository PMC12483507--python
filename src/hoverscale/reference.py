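"""Published hoverfly scaling estimates used as worked-example inputs.

Two regression tables from a comparative study of hovering hoverflies
(Syrphidae; 28 species for morphology, 8 for flight) serve as canonical
inputs for the relative-allometric-scaling-factor machinery:

* ``MASS_SCALING`` — PGLS (Brownian motion) slopes of log10 trait vs log10
  body mass across species means.
* ``FORCE_SCALING`` — OLS slopes of log10 CFD-derived wingbeat-average
  vertical force vs log10 trait for the eight flight species.

Feeding these slopes through :func:`hoverscale.aeroscaling.
relative_scaling_factor` with the model-derived baselines reproduces the
study's per-metric weight-support contributions.
"""

from __future__ import annotations

from .phylostats import ScalingFit

__all__ = ["MASS_SCALING", "FORCE_SCALING"]

#: PGLS-BM regressions of log10 trait on log10 body mass (species means).
MASS_SCALING: dict[str, ScalingFit] = {
    "S2": ScalingFit("S2", 28, 1.008, -2.949, 0.767, 1.250, 0.86, 1e-4, "PGLS-BM"),
    "R": ScalingFit("R", 28, 0.255, -0.479, 0.192, 0.317, 0.84, 1e-4, "PGLS-BM"),
    "c_bar": ScalingFit("c_bar", 28, 0.294, -1.145, 0.229, 0.359, 0.88, 1e-4, "PGLS-BM"),
    "S2_star": ScalingFit("S2_star", 28, -0.034, -0.413, -0.051, -0.018, 0.34, 1e-4, "PGLS-BM"),
    "f": ScalingFit("f", 8, -0.084, 2.343, -0.161, -0.063, 0.09, 0.427, "PGLS-BM"),
    "A_phi": ScalingFit("A_phi", 8, -0.017, 2.041, -0.134, -0.101, 0.01, 0.785, "PGLS-BM"),
    "omega_bar": ScalingFit("omega_bar", 8, -0.101, 10.161, -0.249, -0.046, 0.0, 0.225, "PGLS-BM"),
    "alpha": ScalingFit("alpha", 8, -0.085, 3.947, -0.174, -0.002, 0.22, 0.105, "PGLS-BM"),
}

#: OLS regressions of log10 CFD vertical force on log10 trait (8 species).
FORCE_SCALING: dict[str, ScalingFit] = {
    "S2_omega2": ScalingFit("S2_omega2", 8, 0.989, 3.593, 0.974, 1.005, 1.00, 1e-4, "OLS"),
    "S2": ScalingFit("S2", 8, 1.063, -0.844, 0.667, 1.461, 0.88, 1e-4, "OLS"),
    "f": ScalingFit("f", 8, -0.037, 2.218, -0.238, 0.164, 0.03, 0.667, "OLS"),
    "R": ScalingFit("R", 8, 0.272, 0.058, 0.173, 0.371, 0.88, 1e-4, "OLS"),
    "c_bar": ScalingFit("c_bar", 8, 0.271, -0.525, 0.147, 0.394, 0.83, 0.001, "OLS"),
    "S2_star": ScalingFit("S2_star", 8, -0.031, -0.504, -0.061, 0.000, 0.48, 0.055, "OLS"),
}
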