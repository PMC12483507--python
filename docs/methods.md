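# Methods

This note documents the models, conventions, numerical choices, and known
limitations of `hoverscale`. Units at all public interfaces are field units
(mm, mg, degrees, Hz); the aerodynamic module converts to SI (m, kg, rad, s)
internally.

## Quasi-steady force model and scaling baselines

The wingbeat-average vertical force of one beating wing in hover is modelled
as F̄ = ½ ρ S₂ ω̄² sin(ᾱ) C̄_Fα with ω̄ = 2 f A_φ (the exact cycle mean of
|dφ/dt| for a sinusoidal stroke). The decomposed form substitutes
S₂ = R³ c̄ S₂\* and ω̄ = 2 f A_φ, so both factorisations are algebraically
identical; the code asserts agreement to 1e-12 relative. Total force is
`n_wings` (default 2) times the single-wing force: weight support must be met
by the pair. The factor-of-two bookkeeping is configurable through
`AeroParams.n_wings` because conventions differ between single-wing
simulation studies and whole-animal force balances.

The angle-of-attack-specific force coefficient C̄_Fα defaults to 1.8 (the
order of magnitude measured for flies at these Reynolds numbers); because the
model is linear in C̄_Fα, `calibrate_force_coefficient` can instead set it so
the mass-weighted mean weight-support ratio of a dataset equals 1. The
pipeline calibrates by default, which makes weight-support ratios
interpretable as relative over/under-support; the scaling slopes and a\*
values are invariant to this choice (C̄_Fα only shifts intercepts).

Baselines: under geometric similarity every length scales as m^(1/3), so
R, c̄ ~ m^(1/3), S₂\* ~ m⁰, S₂ ~ m^(4/3); under kinematic similarity
f, A_φ, ω̄, α ~ m⁰. Requiring F ∝ m through allometry of one metric with all
others at similarity gives the single-metric weight-support exponents
(R: 2/9, c̄: 0, S₂\*: −1/3, f, A_φ, ω̄: −1/6, sin α: −1/3). A property test
confirms each exponent numerically: plugging it into the full model over a
log-spaced mass grid yields a log F–log m slope of 1 to 1e-6. The relative
allometric scaling factor a\* = 100(a_allo − a_sim)/(a_ws − a_sim) is linear
in the slope, so contributions of sub-metrics add.

Rounding of percentages follows table convention (half away from zero); the
value is pre-rounded to 9 decimals so exact halves that float arithmetic
lands epsilon below are still treated as halves.

## Wing morphometrics

An outline is a closed simple polygon with a marked hinge vertex. The span
axis is the ray from the hinge through the polygon's area centroid, and R is
the maximum projection of the outline onto it. (The hinge-to-farthest-vertex
convention fails on blunt-tipped shapes, where the farthest vertex is a
corner — a unit square would get R = √1.25 instead of 1; the centroid ray is
exact there and coincides with the hinge-to-tip line for tapered wing
shapes.) The local chord c(r) is the total intersection length of the
polygon with the perpendicular at radial station r, so multi-valued outlines
are handled by summation.

Area S comes from the polygon (shoelace, via shapely) and is cross-checked
against midpoint-rule strip integration of c(r), which must agree within
0.5%; S₂ is the strip sum Σ c(rᵢ) rᵢ² Δr (default 1000 strips; midpoint-rule
error is O(Δr²) and a test asserts monotone convergence over 100/1000/10000
strips). c̄ = S/R and S₂\* = S₂/(R³ c̄), so S₂ = S₂\* R³ c̄ holds exactly by
construction.

Semi-landmarks: one fixed base landmark (the hinge) plus n (default 300)
semi-landmarks, all n+1 points spaced uniformly by arc length (spacing
L/(n+1)) after normalising traversal to counter-clockwise. Uniform spacing of
all points makes resampling idempotent. Semi-landmark *sliding* is not
implemented: the outlines have no homologous curve segments whose sliding
criterion could be anchored, and equidistant spacing is a documented,
reproducible alternative.

Generalised Procrustes analysis removes translation (centroid), size (unit
centroid size), and orientation (SVD rotation, no reflection — mirror left
wings before aligning) against an iteratively re-estimated mean shape;
iteration stops when the mean changes by less than 1e-8 RMS. Because the GPA
optimum is only defined up to a global rotation, the converged mean is
rotated to a canonical orientation (principal axis on +x, sign fixed by the
landmark with the largest axial coordinate), which makes alignment
idempotent and runs reproducible.

Phylogenetic PCA centres the trait (or superimposed-coordinate) matrix on
the GLS mean under the Brownian-motion tip covariance C and eigendecomposes
the C⁻¹-weighted covariance; scores are projections of the GLS-centred data
onto the eigenvectors. On a star phylogeny this is ordinary PCA. Percent
variance is reported over all positive eigenvalues and sums to 100.

## Wingbeat kinematics

Wing orientation is expressed as Euler angles relative to the stroke plane,
which is fixed at 45° to the body long axis through the hinge (hence
β_strokeplane = β_body − 45° exactly). Each angle is fitted with a
fourth-order Fourier series by linear least squares on the raw samples (no
windowing, no uniform-phase resampling). The shared wingbeat period is first
bracketed from successive stroke-angle maxima (FFT fallback for traces
shorter than two maxima) and then refined by minimising the stroke-angle
residual sum of squares over the period (variable projection, bounded scalar
minimisation, tolerance 1e-12 of the period). Using the stroke angle alone
for the period matches stroke-maxima wingbeat segmentation and keeps the
period estimate unbiased when deviation/rotation contain harmonics above the
model order.

Summaries evaluate the fitted curves on a dense one-period grid: amplitudes
are peak-to-peak extrema; ω(t) = √(φ̇² + η̇²); ω̄ = 2 f A_φ by definition;
peak rates are reported for all three angles. The angle-of-attack treats the
wing as a rigid flat plate: sin α = |φ̇ cos θ − η̇ sin θ| / √(φ̇² + η̇²),
with θ = 0 meaning the chord is perpendicular to the stroke plane (so pure
stroke motion gives α = 90° − |θ|). α is undefined (NaN) at stroke reversals
where the wing is momentarily at rest; ᾱ is the mean of α at the two
mid-stroke phases (the extrema of φ̇), where force production peaks. Induced
flow and body motion are ignored in α; the spanwise reference station is
configurable but has no effect for a rigid wing. These are the main
simplifications relative to a full 3-D wake model, and they are shared with
the quasi-steady force model the α feeds into.

Body kinematics: speed from central differences of the tracked position,
climb angle γ = atan2(U_ver, U_hor) (±90° at zero horizontal speed), advance
ratio J = U/(ω̄ R) with ω̄ in rad/s, hovering defined as J < 0.1, and the
sequence-mean frequency f̂ = n_wingbeats/T as a consistency check.

## Phylogenetic statistics

Scaling relations are fitted on log10-transformed species means. PGLS fixes
the Brownian-motion covariance C (no Pagel's λ); the GLS solution is computed
by Cholesky whitening, so a singular C (e.g. duplicated tips at zero
distance) raises a tree-degeneracy error rather than silently regularising.
The residual variance uses the degrees-of-freedom-corrected estimator
(n − 2 denominator) so the t-based 95% CI (n − 2 df, Wald-type) has nominal
coverage under the model; coverage is verified by simulation for OLS
(95% ± 2% at n = 8) and for the full generator → PGLS chain (≥ 90% over 200
replicates per scenario). R² is computed against the GLS intercept-only
model. Allometry is classified from the CI against the similarity exponent
with inclusive bounds (a CI touching a_sim counts as isometry).

Blomberg's K is the observed MSE₀/MSE ratio (deviations from the
phylogenetic mean, raw vs C⁻¹-weighted) standardised by its Brownian-motion
expectation on the same tree, so K ≈ 1 under BM; significance uses
tip-shuffling permutations (default 999) with the plus-one correction,
making the test exact under exchangeability. Covariate adjustment (e.g.
flight speed and climb angle before the mass effect on a kinematic trait)
is an ordinary multiple regression via statsmodels, reporting the mass
coefficient, its p-value, and partial R²; predictor correlations above
0.999 raise a collinearity warning.

## Synthetic data generator

The generator supplies data with the statistical structure the analysis
assumes, not a replica of any real clade.

* **Phylogeny**: pure-birth (Yule) trees, grown one exponential waiting time
  past the n-th speciation so all pendant edges are positive, then rescaled
  to unit root-to-tip depth. Only the induced covariance structure matters
  downstream, and PGLS is invariant to the overall scale of C.
* **Body mass**: log10 mass evolves by Brownian motion (default rate 1 per
  unit depth) and tip values are affinely mapped on the log scale onto the
  configured range (default 3–132 mg, the size span of a diverse hoverfly
  clade). The mapping guarantees masses inside the range while preserving
  the phylogenetic correlations; zero-variance BM degenerates to the
  geometric mean of the range.
* **Wing outlines**: chord profile proportional to a Beta(p, q) density, so
  S₂\* is the Beta second raw moment p(p+1)/((p+q)(p+q+1)) in closed form
  and any target S₂\* can be inverted for p at fixed q (default 2.5).
  Shape parameters below 1 are rejected (unbounded chord at hinge or tip).
  The polygon's enclosed area is normalised to R·c̄ exactly; chord rescaling
  cancels in S₂\*, so the closed form is untouched.
* **Wingbeat traces**: stroke = pure fundamental (peak-to-peak A_φ, default
  100°); deviation = small fundamental + second harmonic (default 10°);
  rotation = third-harmonic-flattened square wave θ_m(9/8 sin + 1/8 sin 3)
  whose plateau sets the mid-stroke angle-of-attack (default 42°). All
  templates are band-limited to harmonic order ≤ 3, so the fourth-order
  Fourier pipeline reproduces f, A_φ, and α_mid exactly at zero noise —
  the noiseless round trip is a calibration property, not a tautology,
  because the estimation path (period search, least squares, extrema,
  α geometry) is independent of the templates.
* **Scenarios**: `isometry` (R, c̄ ~ m^(1/3), everything else flat),
  `morphology_compensated` (R ~ m^(2/9) so S₂ ~ m; the wingspan exponent is
  re-solved if a nonzero S₂\* exponent is configured), and
  `kinematics_compensated` (morphology isometric, f ~ m^(−1/6)). With zero
  noise every trait's log–log slope equals its scenario exponent exactly.
* **Noise**: trait scatter is log-normal (SD in log10 units, default 0.02 —
  roughly ±5% multiplicative scatter, a deliberately modest interspecific
  residual since no empirical intraspecific variances are available to
  emulate; it is a free parameter of the config). Angle noise is Gaussian
  in degrees (default 2°). Trait residuals are independent across species;
  real comparative residuals may themselves be phylogenetically
  correlated, which the generator does not emulate.

What passing tests on these data do *not* show: robustness to tracking
error structure in real videos, wing deformation (wings are rigid flat
plates throughout), asymmetric real outlines (the centroid span axis is
exact only for chordwise-symmetric shapes), or misspecified phylogenies.

## Pipeline conventions

All randomness flows from one seed through named substreams, and CSV floats
are written at 6 significant digits, so a config + seed reproduces outputs
byte for byte. Stage failures carry the stage name and offending record id.
The headline a\* decomposition uses the mass-based PGLS slopes (meaningful
in every scenario); a second decomposition from the force-based OLS slopes
(each metric regressed on the model force, an analysis that presumes
weight support) is reported alongside. Default problem sizes —
28 species, 3 wingbeats per trace at 40 samples per wingbeat, 1000
integration strips, 999 permutations — keep a full pipeline run around a
second while leaving all Monte-Carlo checks comfortably resolved.
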