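"""End-to-end orchestration: data -> morphology -> kinematics -> aerodynamics
-> scaling fits -> weight-support decomposition report.

``run_pipeline`` drives the whole analysis either on a synthetic species set
(:mod:`hoverscale.synthgen`) or on user files (Newick tree, trait CSV,
outline CSVs, wingbeat trace CSVs).  Output is a JSON report plus CSV tables
with 6-significant-digit floats, byte-reproducible for a fixed config/seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from . import aeroscaling, kinematics, phylostats, synthgen, wingmorph
from .aeroscaling import AeroParams
from .errors import HoverscaleError, InvalidParameterError, StageError
from .synthgen import ScenarioConfig
from .trees import tree_from_newick

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("hoverscale")

FLOAT_FORMAT = "%.6g"

#: traits regressed against body mass (PGLS), with their similarity exponents
MASS_METRICS = ("S2", "R", "c_bar", "S2_star", "f", "A_phi", "omega_bar", "alpha")
#: metrics regressed against model force (OLS)
FORCE_METRICS = ("S2_omega2", "S2", "f", "R", "c_bar", "S2_star")

_TRAIT_COLUMNS = {
    "S2": "S2_mm4", "R": "R_mm", "c_bar": "cbar_mm", "S2_star": "S2star",
    "f": "f_Hz", "A_phi": "Aphi_deg", "omega_bar": "omega_deg_s",
    "alpha": "alpha_deg",
}


@dataclass
class PipelineConfig:
    mode: str = "synthetic"                    # "synthetic" | "files"
    scenario: ScenarioConfig | None = None     # required for synthetic mode
    aero: AeroParams = field(default_factory=AeroParams)
    calibrate_cf: bool = True                  # fit C_F_alpha to mean weight support
    outdir: str | Path = "hoverscale_out"
    seed: int = 0
    n_strips: int = 1000
    n_permutations: int = 999
    paths: dict = field(default_factory=dict)  # tree/traits/outlines/traces for files mode

    def __post_init__(self):
        if self.mode not in ("synthetic", "files"):
            raise InvalidParameterError("mode must be 'synthetic' or 'files'")
        if self.mode == "synthetic" and self.scenario is None:
            self.scenario = ScenarioConfig(seed=self.seed)
        if self.mode == "files":
            missing = {"tree", "traits"} - set(self.paths)
            if missing:
                raise InvalidParameterError(f"files mode needs paths: {sorted(missing)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise InvalidParameterError("config must set a seed")
        if "scenario" in raw and raw["scenario"] is not None:
            sc = dict(raw["scenario"])
            sc.setdefault("seed", raw["seed"])
            if "mass_range" in sc:
                sc["mass_range"] = tuple(sc["mass_range"])
            raw["scenario"] = ScenarioConfig(**sc)
        if "aero" in raw and raw["aero"] is not None:
            raw["aero"] = AeroParams(**raw["aero"])
        return cls(**raw)


def _timer(stage: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: %.2f s", stage, time.perf_counter() - self.t0)
            return False

    return _T()


def _load_files(cfg: PipelineConfig):
    try:
        tree = tree_from_newick(Path(cfg.paths["tree"]).read_text())
    except Exception as exc:
        raise StageError("simulate", f"cannot read tree: {exc}",
                         record=str(cfg.paths["tree"])) from exc
    try:
        traits = pd.read_csv(cfg.paths["traits"])
    except OSError as exc:
        raise StageError("simulate", f"cannot read trait table: {exc}",
                         record=str(cfg.paths["traits"])) from exc
    return tree, traits


def _read_outline(path: Path, specimen_id: str) -> wingmorph.WingOutline:
    df = pd.read_csv(path)
    hinge = int(np.flatnonzero(df["is_hinge"].to_numpy())[0]) if "is_hinge" in df else 0
    return wingmorph.WingOutline(
        points=df[["x_mm", "y_mm"]].to_numpy(dtype=float),
        hinge_index=hinge, specimen_id=specimen_id,
    )


def _species_outline(row: pd.Series) -> wingmorph.WingOutline:
    p, q = synthgen.beta_shape_for_s2star(float(row["S2star"]))
    return synthgen.synth_wing_outline(
        R=float(row["R_mm"]), c_bar=float(row["cbar_mm"]),
        beta_p=p, beta_q=q, n_points=300, specimen_id=str(row["species"]),
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the report dict and writes all outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "mode": config.mode}

    # ---- stage: simulate / load -------------------------------------------
    with _timer("simulate"):
        if config.mode == "synthetic":
            tree, traits = synthgen.generate_species_set(config.scenario)
            synthgen.write_species_set(tree, traits, outdir, config.scenario)
            report["scenario"] = config.scenario.to_dict()
        else:
            tree, traits = _load_files(config)
        traits = traits.set_index("species", drop=False)

    # ---- stage: morphology ------------------------------------------------
    with _timer("morphology"):
        morph_rows = []
        for sp, row in traits.iterrows():
            try:
                if config.mode == "files":
                    outline = _read_outline(
                        Path(config.paths["outlines"]) / f"{sp}.csv", str(sp))
                else:
                    outline = _species_outline(row)
                summ = wingmorph.morphology_from_outline(
                    outline, mass=float(row["mass_mg"]), n_strips=config.n_strips)
            except (HoverscaleError, OSError) as exc:
                raise StageError("morphology", str(exc), record=str(sp)) from exc
            morph_rows.append({"species": sp, **summ.as_dict()})
        morph = pd.DataFrame(morph_rows).set_index("species", drop=False)

    # ---- stage: kinematics ------------------------------------------------
    with _timer("kinematics"):
        kin_rows = []
        body_rows = []
        for i, (sp, row) in enumerate(traits.iterrows()):
            try:
                if config.mode == "files":
                    trace = kinematics.WingbeatTrace.from_frame(
                        pd.read_csv(Path(config.paths["traces"]) / f"{sp}.csv"))
                else:
                    trace = synthgen.synth_wingbeat_trace(
                        f=float(row["f_Hz"]), A_phi=float(row["Aphi_deg"]),
                        alpha_mid=float(row["alpha_deg"]),
                        kin_noise_sd=config.scenario.kin_noise_sd,
                        seed=config.seed * 100003 + i,
                    )
                fit = kinematics.fit_wingbeat_fourier(trace)
                summ = kinematics.derive_wingbeat_summary(fit)
                # body track: stationary hover unless files provide one
                if config.mode == "files" and "body" in config.paths:
                    body = pd.read_csv(Path(config.paths["body"]) / f"{sp}.csv")
                else:
                    body = pd.DataFrame({
                        "t_s": trace.t, "x_m": 0.0, "y_m": 0.0, "z_m": 0.0,
                        "body_pitch_deg": 30.0,
                    })
                n_beats = max(round((trace.t[-1] - trace.t[0]) * summ.f), 1)
                bsumm = kinematics.body_kinematics_summary(
                    body, n_wingbeats=n_beats,
                    omega_bar_rad=summ.omega_bar_rad,
                    R_m=float(morph.loc[sp, "R_mm"]) * 1e-3,
                )
            except (HoverscaleError, OSError) as exc:
                raise StageError("kinematics", str(exc), record=str(sp)) from exc
            kin_rows.append({"species": sp, **summ.as_dict()})
            body_rows.append({"species": sp, **bsumm.as_dict()})
        kin = pd.DataFrame(kin_rows).set_index("species", drop=False)
        body = pd.DataFrame(body_rows).set_index("species", drop=False)
        report["hovering"] = {
            "n_wingbeats": int(len(body)),
            "n_hovering": int(body["hovering"].sum()),
            "pass_rate": float(body["hovering"].mean()),
            "mean_J": float(body["J"].mean()),
        }

    # ---- stage: aerodynamics ----------------------------------------------
    with _timer("aero"):
        S2_si = morph["S2_mm4"].to_numpy() * 1e-12           # mm^4 -> m^4
        omega = kin["omega_rad_s"].to_numpy()
        alpha = np.deg2rad(kin["alpha_deg"].to_numpy())
        mass = traits["mass_mg"].to_numpy(dtype=float)
        params = config.aero
        if config.calibrate_cf:
            params = aeroscaling.calibrate_force_coefficient(
                S2_si, omega, alpha, mass, params)
        F_total = np.array([
            aeroscaling.quasi_steady_force(s2, w, a, params)[1]
            for s2, w, a in zip(S2_si, omega, alpha)
        ])
        ws = np.array([
            aeroscaling.weight_support_ratio(F, m, params)
            for F, m in zip(F_total, mass)
        ])
        f_mean = float(kin["f_Hz"].mean())
        report["aero"] = {
            "C_F_alpha": params.C_F_alpha,
            "calibrated": bool(config.calibrate_cf),
            "f_mean_Hz": f_mean,
            "weight_support": {
                sp: float(w) for sp, w in zip(traits["species"], ws)
            },
        }

    # ---- stage: scaling ---------------------------------------------------
    with _timer("scaling"):
        species = list(traits["species"])
        values = {
            "S2": morph["S2_mm4"], "R": morph["R_mm"], "c_bar": morph["cbar_mm"],
            "S2_star": morph["S2star"], "f": kin["f_Hz"], "A_phi": kin["Aphi_deg"],
            "omega_bar": kin["omega_deg_s"], "alpha": kin["alpha_deg"],
            "S2_omega2": morph["S2_mm4"] * kin["omega_rad_s"] ** 2,
        }
        mass_s = pd.Series(mass, index=species)
        mass_fits: dict[str, phylostats.ScalingFit] = {}
        for metric in MASS_METRICS:
            y = pd.Series(values[metric].to_numpy(), index=species)
            try:
                fit = phylostats.pgls_loglog(tree, mass_s, y, metric=metric)
            except HoverscaleError as exc:
                raise StageError("scaling", str(exc), record=metric) from exc
            mass_fits[metric] = fit
        # metric is the response, force the predictor: with weight support
        # (F ~ m g) these slopes parallel the mass-based allometric slopes
        force_s = pd.Series(F_total, index=species)
        force_fits: dict[str, phylostats.ScalingFit] = {}
        for metric in FORCE_METRICS:
            y = pd.Series(values[metric].to_numpy(), index=species)
            force_fits[metric] = phylostats.ols_loglog(force_s, y, metric=metric)

        classifications = {
            m: phylostats.allometry_classify(
                fit, aeroscaling.expected_exponents(m).a_sim)
            for m, fit in mass_fits.items()
        }
        signals = {}
        for j, metric in enumerate(("S2", "R", "c_bar", "S2_star", "f")):
            trait = pd.Series(values[metric].to_numpy(), index=species, name=metric)
            if np.ptp(trait.to_numpy()) == 0:
                signals[metric] = {"K": None, "p": None, "n_perm": 0,
                                   "note": "zero-variance trait"}
                continue
            res = phylostats.blomberg_k(
                tree, trait, n_perm=config.n_permutations,
                seed=config.seed * 7919 + j)
            signals[metric] = {"K": res.K, "p": res.p, "n_perm": res.n_permutations}

        # headline decomposition from the mass-based PGLS slopes; the
        # force-based variant is meaningful when weight support holds
        decomposition = aeroscaling.contribution_decomposition(
            {m: mass_fits[m] for m in ("S2", "f", "R", "c_bar", "S2_star")})
        decomposition_force = aeroscaling.contribution_decomposition(force_fits)
        report["scaling_vs_mass"] = {
            m: {**f.as_dict(), "a_sim": aeroscaling.expected_exponents(m).a_sim,
                "a_ws": aeroscaling.expected_exponents(m).a_ws,
                "allometry": classifications[m]}
            for m, f in mass_fits.items()
        }
        report["scaling_vs_force"] = {m: f.as_dict() for m, f in force_fits.items()}
        report["phylogenetic_signal"] = signals
        def _decomp_dict(d):
            return {
                "per_metric": {
                    m: dataclasses.asdict(c) for m, c in d.per_metric.items()
                },
                "components": list(d.components),
                "component_sum_percent": d.component_sum,
                "component_sum_rounded": d.component_sum_rounded,
            }

        report["decomposition"] = _decomp_dict(decomposition)
        report["decomposition_vs_force"] = _decomp_dict(decomposition_force)

    # ---- stage: report ----------------------------------------------------
    with _timer("report"):
        def _tbl(fits: dict, extra=None) -> pd.DataFrame:
            rows = []
            for m, f in fits.items():
                row = f.as_dict()
                if extra:
                    row.update(extra(m, f))
                rows.append(row)
            return pd.DataFrame(rows)

        morph.drop(columns="species").to_csv(
            outdir / "morphology.csv", float_format=FLOAT_FORMAT)
        kin.drop(columns="species").to_csv(
            outdir / "kinematics.csv", float_format=FLOAT_FORMAT)
        body.drop(columns="species").to_csv(
            outdir / "body_kinematics.csv", float_format=FLOAT_FORMAT)
        _tbl(mass_fits, lambda m, f: {
            "a_sim": aeroscaling.expected_exponents(m).a_sim,
            "a_ws": aeroscaling.expected_exponents(m).a_ws,
            "allometry": classifications[m],
        }).to_csv(outdir / "scaling_vs_mass.csv", index=False,
                  float_format=FLOAT_FORMAT)
        _tbl(force_fits).to_csv(outdir / "scaling_vs_force.csv", index=False,
                                float_format=FLOAT_FORMAT)
        pd.DataFrame(decomposition.as_records()).to_csv(
            outdir / "decomposition.csv", index=False, float_format=FLOAT_FORMAT)
        pd.DataFrame(decomposition_force.as_records()).to_csv(
            outdir / "decomposition_vs_force.csv", index=False,
            float_format=FLOAT_FORMAT)
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=float))
    return report
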