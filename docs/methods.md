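# Methods

This note documents the models, the numerical choices and the limits of
what the package's tests demonstrate.

## Synthetic anatomy

The template is a fixed-topology biventricular mesh built from two
thick-walled truncated ellipsoidal shells: an LV (endocardial semi-axes
27/27/46 mm, wall 10 mm) and a thinner RV shell (30/30/44 mm, wall 4.5 mm)
offset 75 mm laterally.  Each shell is discretised on a structured
(polar angle × azimuth × transmural) grid with a pole node line at the
apex; hexahedral cells are split into five tetrahedra with parity-alternating
diagonals so neighbouring cells conform, and apex prisms into three.  At the
default 8 mm target edge length the mesh has ≈1300 nodes and ≈3100 positive-
quality tetrahedra, a size at which the full study runs in seconds.  A wall
that would receive less than one element through its thickness is rejected.

Per-node metadata (ventricle, transmural depth, azimuth, apicobasal
coordinate Z ∈ [0,1], endocardial flag, outward endocardial normal) is kept
on the mesh and drives both the deformations and the electrophysiology.
The closed endocardial surfaces (shell + apex fan + flat basal lid) support
divergence-theorem cavity volumes.

**Latent factors.**  Five factors deform the template: global scale,
sphericity, LV wall thickness, whole-heart orientation, and a
Gaussian-windowed inward bulge on septal LV nodes with Z > 0.8.  All
non-rigid factors act as additive displacement fields evaluated on the
template geometry, hence *exactly linear* in their factor; sphericity
multiplies the long axis by `2 − sphericity` (a linear shortening) rather
than a ratio for the same reason.  This linearity is what makes shape-model
recovery exact: a noiseless cohort driven by k linear factors has a point
matrix of rank k, and PCA recovers the factor span to machine precision.
Rotation is applied last and rigidly; it is the one factor a linear model
cannot represent exactly, which is deliberate — real registration residuals
behave the same way.

Cohort sampling draws independent zero-mean Gaussians per factor.  Latent
SDs are dimensionless, non-increasing (default 0.10, 0.07, 0.05, 0.035,
0.025), and each factor's physical unit is chosen so one latent unit
produces comparable RMS node displacement (scale 1/unit, sphericity 1/unit,
LV wall 20 mm/unit, orientation 100°/unit, bulge 40 mm/unit).  The bulge
draw is folded to its absolute value because the bulge is an inward
displacement by construction.  Node jitter (default 0.25 mm iid) models
segmentation noise.  Default cohort size is 19.

**What the generator does not emulate:** four-chamber topology, atria and
vessels, a crescent RV wrapped around the septum (the RV is a free-standing
shell), real registration error structure, or population covariance between
factors.  Tests passing on these cohorts show the *machinery* is correct,
not that real anatomies satisfy the linear-factor assumptions.

## Shape model

Rigid alignment is least-squares rotation+translation (Kabsch; no scaling,
so size differences survive into mode space).  The model is a PCA of the
n × 3N displacement matrix from the cohort mean, computed by SVD; all
nonzero modes are retained, weights reproduce each case exactly, and the
sign convention (largest-magnitude coordinate of each mode positive) fixes
the arbitrary PCA sign for reproducibility.  Per-mode SDs use the (n−1)
denominator.  Extreme anatomies are `mean ± k·SD·mode` for k ∈ {1,2,3};
meshes whose elements invert are emitted flagged rather than dropped, so a
cohort's completion accounting stays faithful.  Weights are available raw
and in SD units.

## Electromechanics surrogate

**Activation.**  Activation time is the exact multi-source shortest path
over the mesh edge graph (Dijkstra), edge time = length/CV.  An edge belongs
to the fast endocardial conduction (FEC) layer iff both endpoints are
endocardial with Z ≤ 0.7 (inclusive; the boundary convention is explicit).
Defaults: myocardial CV 0.6 mm/ms, FEC CV 3.0 mm/ms, stimulus at apical
endocardial nodes (Z ≤ 0.1) of both ventricles.  Eikonal linearity makes
all times scale exactly as 1/CV when all velocities scale together.

**Active stress.**  `T(t) = T_peak · tanh²(e/τ_c) · tanh²((t_dur−e)/τ_r)`
for elapsed time e ∈ (0, t_dur) after trigger+delay, zero outside; bounded
by T_peak and continuous.  Each ventricle triggers at its *mean* activation
time — the single point of EP→mechanics coupling a 0D model supports; this
is a documented limitation, not an approximation that can be refined here.
Active tension additionally scales with a linear force–length factor in the
normalised cavity stretch λ = (V/EDV)^{1/3}, zero below λ₀ = 0.6.  Without
this Frank–Starling mechanism the thick-wall-sphere model is unstable: its
Laplace factor grows as the cavity empties, so contraction would run away
to zero volume.

**Mechanics and circulation.**  Each ventricle is a thick-walled sphere
with conserved wall volume; cavity pressure is
`P = (σ_passive + σ_active) · 2h/r_m` (kPa→mmHg), with
`σ_passive = a (exp[b(V/V₀ − 1)] − 1)`, scale a = 0.30 kPa, exponent b = 5,
and unloaded volume V₀ = EDV/1.45 — chosen so the passive pressure at EDV
equals the preload, making end-diastole an equilibrium.  Valves are ideal
diodes with 5 mmHg·ms/mL forward resistance; ejection feeds a three-element
Windkessel (systemic: 50/1100 mmHg·ms/mL, 1.6 mL/mmHg; pulmonary:
15/150 mmHg·ms/mL, 5 mL/mmHg); filling comes from constant preloads
(10/5 mmHg).  Integration is explicit Euler, dt = 0.1 ms over 800 ms;
valve event times are linearly interpolated at the pressure-gradient zero
crossing, which is what keeps every timing phenotype grid-converged to
<0.5% under dt halving.  The cardiac phases emerge from the diode logic;
with both valves closed the volume is constant *exactly*, and the discrete
flow integrals reproduce the volume change identically by construction.

Peak tension (42 kPa) is the one deliberately calibrated constant: it puts
the template LV ejection fraction at ≈56%, inside the normal physiological
band; all other defaults are literature-scale values.  A beat reaching a
non-finite state or non-positive volume is flagged incomplete and excluded
from downstream statistics — the cohort run never aborts.

**Out of scope by design:** 3D finite-element mechanics, fibre anisotropy,
ionic models, unloading to a stress-free reference, pericardial and atrial
mechanics (atria are a constant preload), closed-loop circulation.

## Phenotypes

Definitions are in the module docstring.  Choices the definitions leave
open: tsys := ICT + ET; ESP is the pressure at outflow-valve closure (not a
flow-derived end of systole); AT1090 uses nearest-rank order statistics;
dP/dt uses centred differences (one-sided endpoints); QRS is the full
ventricular activation span, since the surrogate has no ECG.

## Sensitivity

*Range filter:* `(max − min)/|mean|`, discard strictly below 0.2.  The
absolute value makes sign-definite negative phenotypes (dPdtmin) be judged
on magnitude; a signed mean would discard them unconditionally.

*Correlations:* Pearson by default (Spearman available), completed cases
only; per-mode summary is mean ± SD of |R| across phenotypes.

*GPE:* anisotropic RBF + constant + white-noise kernel on per-mode
standardised inputs and standardised outputs.  Leave-one-out CV runs over
imaged cases only, with every synthetic case always in training; the
reported model refits all data with the hyperparameters of the
smallest-error split (the mean-MSE alternative would be a one-line change).
Kernel-optimisation failures fall back to default hyperparameters with a
warning.

*Sobol/Saltelli:* the design is exactly (2D+2)·N rows
([A; B; AB₁..AB_D; BA₁..BA_D]) from a scrambled Sobol sequence; S1 uses the
Saltelli-2010 estimator averaged over the AB and BA blocks, ST the Jansen
estimator.  Input distribution is uniform over the per-mode range of the
imaged cohort.  The "multifactorial" share is max(0, 1 − ΣS1).  The
implementation is verified against the closed-form Ishigami indices and an
additive-model no-interaction check.

*Local sensitivity:* SC = (x₀/y₀)(y₊ − y₋)/(x₊ − x₋) at ±10%.  In the LSA
battery the FEC conduction velocity is parametrised as a *ratio* to the
myocardial CV: perturbing myocardial CV then rescales the whole conduction
field, so activation times scale exactly as 1/CV and the coefficient for
LV total activation time is −(1/1.1 − 1/0.9)/0.2 = −1.01; perturbing the
ratio isolates the endocardial layer (and reproduces the weaker ≈ −0.2
to −0.8 coefficients a fixed FEC CV would show).  Parameters with no model
pathway to a phenotype give SC = 0 to integrator noise.

## Problem sizes and determinism

Default sizes — 8 mm template (~1300 nodes), 19-case cohorts, Sobol
N = 256 for emulated GSA (4096 for the analytic Ishigami battery) — were
chosen so the full pipeline and test suite run in well under a minute each
while every oracle retains its stated tolerance.  All stochastic stages
(cohort draws, Sobol scrambling, GP optimiser restarts) take explicit
seeds; a fixed run config regenerates byte-identical tables.

## Known limitations

The surrogate has no spatial mechanics, so phenotypes sensitive to regional
dyssynchrony respond to shape only through lumped geometry (volumes, wall
volume, mean activation time).  The RV shell's pressures are those of a
free-standing sphere, not a septum-coupled crescent.  The synthetic
cohort's factor structure is known and mostly linear, which is exactly what
makes recovery tests sharp — and exactly what real cohorts violate.
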