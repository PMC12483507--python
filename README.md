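# hoverscale

Evolutionary allometry of hovering flight: do species compensate for body-size
variation with their **wing morphology** or with their **wingbeat kinematics**?

Hovering insects such as hoverflies (Syrphidae) must balance their weight with
the lift of their flapping wings. Quasi-steady aerodynamics gives the
wingbeat-average vertical force of a beating wing as

    F̄ = ½ ρ S₂ ω̄² C̄_F ,   C̄_F = sin(ᾱ) C̄_Fα ,   ω̄ = 2 f A_φ

with air density ρ, wing second-moment-of-area S₂ = ∫ c(r) r² dr, and
wingbeat-average angular speed ω̄ set by frequency f and stroke amplitude A_φ.
Substituting S₂ = R³ c̄ S₂\* separates size (span R, mean chord c̄) from shape
(the dimensionless S₂\*). Under geometric similarity S₂ ~ m^(4/3): force drops
faster than weight as size shrinks, so small species must deviate somewhere —
disproportionately large or distally loaded wings, or faster wingbeats.

The package quantifies *where* the compensation happens. For each metric with
observed allometric slope `a_allo` (log–log regression across species), a
similarity exponent `a_sim`, and the single-metric weight-support exponent
`a_ws` (the slope that metric alone would need for F ∝ m, e.g. R ~ m^(2/9),
f ~ m^(−1/6)), the **relative allometric scaling factor**

    a* = 100 · (a_allo − a_sim) / (a_ws − a_sim)   [%]

is the percentage of weight-support compensation that metric's allometry
provides (0% = pure similarity, 100% = full single-metric compensation).

## What is in the box

| module | contents |
| --- | --- |
| `hoverscale.synthgen` | pure-birth phylogenies, Brownian-motion body masses, Beta-profile wing outlines with closed-form S₂\*, periodic wingbeat traces; three generative scaling scenarios |
| `hoverscale.wingmorph` | S, R, c̄, S₂, S₂\* from outline polygons; 300 semi-landmark resampling; `GeneralizedProcrustes` and `PhylogeneticPCA` transformers |
| `hoverscale.kinematics` | fourth-order Fourier fits of stroke/deviation/rotation angles, wingbeat-average summaries (ω̄ = 2 f A_φ, mid-stroke angle-of-attack), advance ratio J and the J < 0.1 hovering filter |
| `hoverscale.aeroscaling` | the force model and its decomposition, similarity / weight-support baselines, a\*, contribution decomposition, force-coefficient calibration |
| `hoverscale.phylostats` | `ScalingRegression` (OLS and PGLS under Brownian motion), Blomberg's K with permutation test, allometry classification, covariate adjustment |
| `hoverscale.pipeline` / CLI | end-to-end orchestration and the `hoverscale` command (`simulate`, `morphology`, `kinematics`, `scaling`, `report`, `all`) |

Regression, Procrustes and PCA components are scikit-learn-style estimators
(`fit` / `transform`, `get_params`, trailing-underscore attributes) and compose
with sklearn tooling; module-level functions wrap them for one-shot use.

## Worked example

Run the full pipeline on a synthetic 28-species clade in which wing morphology
alone compensates for size (masses 3–132 mg, trait scatter 0.02 log10 units,
2° angle noise):

```sh
cat > demo.yaml <<EOF
mode: synthetic
seed: 1
scenario:
  n_species: 28
  scenario: morphology_compensated
  noise_sd_log10: 0.02
  kin_noise_sd: 2.0
EOF
hoverscale all --config demo.yaml --out demo_out
```

The PGLS fits against body mass in `demo_out/scaling_vs_mass.csv` recover the
generative structure:

```
S2       slope +1.017  CI [+0.944, +1.090]  a_sim +1.33  a_ws +1.00  negative
R        slope +0.226  CI [+0.207, +0.246]  a_sim +0.33  a_ws +0.22  negative
c_bar    slope +0.324  CI [+0.293, +0.356]  a_sim +0.33  a_ws +0.00  isometry
f        slope +0.013  CI [-0.019, +0.045]  a_sim +0.00  a_ws -0.17  isometry
```

S₂ scales with mass with exponent ≈ 1 — significantly below the isometric 4/3
(negative allometry), right at the weight-support slope — and wingbeat
frequency shows no mass dependence. The decomposition report turns this into
contributions: a\*(S₂) = 95%, a\*(R) = 96%, a\*(f) = −8% (noise around zero),
i.e. wing morphology, dominated by wingspan, carries essentially all of the
compensation. The calibrated force coefficient is C̄_Fα = 1.14 and every
synthetic wingbeat passes the hovering filter (J < 0.1).

Feeding published hoverfly regression slopes through the same machinery
(`hoverscale.reference`, `hoverscale report --fits ...`) reproduces the
published per-metric contributions and their 105% component sum.

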