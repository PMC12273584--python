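# Methods

This note documents the models implemented in `liggrad`, their
assumptions, the defaults that matter, and the numerical choices — in the
spirit of a model-documentation page rather than a tutorial.

## Geometry and units

All spatial models assume spherical symmetry: a cell of radius *a*
(default 10 μm) at the origin, with the extracellular space extending to an
outer radius (default 100 μm for simulations).  This idealizes an adherent
monolayer but keeps every profile one-dimensional in the radial coordinate
*r*.  Because experimental profiles are reported as distance from the
membrane, every `RadialProfile` exposes both *r* and *d = r − a*.

Concentrations appear in three tagged units: particles per confocal volume
(the native FCS readout), particles/μm³, and nM.  Conversions use
V_C = 0.16 μm³ as the default confocal volume and
1 nM = 0.6022 particles/μm³ (10⁻⁹ mol/L · N_A · 10⁻¹⁵ L/μm³); with these,
1 particle per confocal volume ≈ 10.4 nM.

## FCS model and fitting

The autocorrelation model is a single free 3-D diffusion component with a
triplet-blinking prefactor (parameters: particle number N, triplet
fraction T and correlation time τ_triplet, diffusion correlation time τ_D,
beam shape κ).  Fits are unweighted least squares (lmfit/Levenberg–
Marquardt, xtol = ftol = 10⁻¹⁴), with starting values derived from the
curve itself: N from the zero-lag amplitude, τ_D from the half-decay lag,
T = 0.1.

Two constraints are fitting policy, not physics:

* **κ is fixed by default** (κ = 5, configurable).  κ and τ_D are only
  weakly identifiable jointly; fixing κ is standard FCS practice.
* **T is bounded to [0, 0.5]** to prevent the triplet term from exchanging
  amplitude with the diffusion term on noisy curves.

A curve with no decay (G ≡ 1) raises an explicit `FitFailure` rather than
returning defaults.  Beam calibration fits a reference-dye curve of known
diffusion coefficient (Alexa Fluor 546, 341 μm²/s at 25 °C) and inverts
D = ω²/(4τ_D); the confocal volume follows as π^{3/2}κω³.

## Fick steady state and membrane flux

With constant D, a stable membrane-proximal gradient (c_m at the membrane,
c_0 in the bulk) must satisfy c(r) = a(c_m − c_0)/r + c_0 and requires a
sustained outward membrane flux J = D(c_m − c_0)/a.  With the measured
values (c_m = 3, c_0 = 1 particles per 0.16 μm³, i.e. 18.75 and
6.25 μm⁻³; D = 150 μm²/s) this gives J = 187.5 μm⁻²s⁻¹ at a = 10 μm and
625 μm⁻²s⁻¹ at a 3 μm length scale.  Both numbers are exposed; the choice
of length scale is the only difference between them, and the package does
not privilege either.

## Fokker–Planck steady state with varying diffusivity

Where diffusivity varies in space, the stationary distribution satisfies
∇²(Dc) = 0, i.e. r²·d(Dc)/dr = K₃.  The measured D(r) dip is modelled as a
parabola D(r) = p₁(r − p₂)² + p₃ (defaults p₁ = 0.32 s⁻¹, p₂ = 23.47 μm,
p₃ = 91.32 μm²/s, from the fitted experimental profile), giving the closed
form c(r) = (K₄r − K₃)/(D(r)·r).  K₃ and K₄ are **always recomputed** from
the user's two Dirichlet boundary conditions by an exact 2×2 linear solve;
previously published constants for the default model are retained as
reference metadata only, since they are not consistent with the rounded
p₁–p₃ to better than a few percent.  With the default model and
c(13) = c(35) = 2 the solve gives K₃ ≈ 308.7, K₄ ≈ 276.5 and an interior
maximum c ≈ 2.89 at r ≈ 23.5 μm — about one extra particle per confocal
volume, the magnitude of the observed membrane-distal peak.  The parabola
fit (`fit_diffusivity_model`) is performed in original space via an exact
quadratic polynomial solve, refined under a p₃ > 0 bound only when needed;
a near-zero curvature makes p₂ meaningless and is flagged
(`p2_identifiable=False`) rather than guessed.

## Reaction–diffusion simulator

The three coupled fields are free ligand L (diffusing), liganded receptor
LR and free receptor R (both immobile).  Receptor fields are nonzero only
within a membrane shell whose thickness defaults to one grid cell — the
narrative "receptors at the plasma membrane" mapped onto a volume
discretization; the thickness is a parameter because any finite shell is a
modelling choice.

**Discretization.**  Conservative finite volumes on uniform spherical
shells: interface fluxes −D·ΔL/Δr times interface area 4πr², divided by
shell volumes (4π/3)(r³ᵢ₊₁ − r³ᵢ).  This conserves ligand to solver
tolerance with zero-flux boundaries.  Time integration is implicit BDF
(`scipy.integrate.solve_ivp`) with a sparse Jacobian pattern
(tridiagonal in L, diagonal couplings to LR/R), rtol = 10⁻⁶,
atol = 10⁻⁹ nM.  Default grid: 400 cells on [10, 100] μm; doubling the
resolution changes reported equilibria by < 0.2%.

**Boundary conditions.**  Zero flux at both ends for scenarios 1–3; for
scenario 4 an imposed outward ligand flux J at r = a and a Dirichlet
condition (fixed c₀) at the outer edge, implemented with a half-cell ghost
gradient.  Instantaneous additions (receptor introduction, exocytosis
pulse) are initial conditions at t = 0, not delta sources.

**Kinetics defaults.**  D = 150 μm²/s (measured), k_on = 0.0023 (nM·s)⁻¹,
k_off = 0.003 s⁻¹ (literature EGF–EGFR values), hence K_d ≈ 1.30 nM.

**Receptor load.**  The receptor surface density is not an independent
dial: for scenario 1 (and the pre-equilibrated scenarios 3–4) it is derived
from a requested equilibrium ligand depletion (default 10%) by inverting
the 0-D conservation law L₀V = L_eqV + R_T·L_eq/(K_d + L_eq)·V_shell —
the same law serves as the independent oracle the PDE equilibrium is tested
against (agreement within 0.5%).

**Scenario-4 source magnitude.**  No measured influx exists; the default
J = 2c₀D/a makes the steady membrane concentration ≈2.8× bulk, matching
the observed ~3-fold proximal enrichment scale.  The simulated steady
state is verified against the closed form
c(r) = c₀ + (Ja²/D)(1/r − 1/R_out) to better than 1%.

The physical conclusions the scenarios encode: equilibrium binding alone
(scenarios 1–3) produces only transient peaks — negative when unliganded
receptor is introduced, positive after an exocytosis pulse — and always
relaxes to a spatially uniform free-ligand field; only a continuous
membrane source (scenario 4) sustains a permanent peak.

## Binding distortion and budgets

The apparent-affinity analysis rests on an algebraic identity: if membrane
concentration relates to bulk as c_mem = A·c_bulk^b, then Hill saturation
read against bulk concentration is again exactly Hill, with n_app = n·b
and K_d,app = (K_d/A)^{1/b}.  The fit-based `apparent_experiment` is
checked against this closed form to 10⁻⁶ — the module's core correctness
oracle.  The default mapping (A ≈ 9, b ≈ 0.523) is **reconstructed** from
two reported observations (3-fold enrichment at 10 nM bulk, none at
100 nM) because the originally fitted mapping parameters were not
published; it reproduces the direction of the distortion (higher apparent
affinity, lower apparent cooperativity), not a specific published pair of
apparent values.  In-silico titrations use 12 log-spaced concentrations
from 0.01 to 100 nM.  Hill fits are parameterized in log K_d; a free
maximal-amplitude parameter is available for normalized experimental data.

The budget calculators are exact arithmetic: release totals
(flux·area·duration·cells, → moles and bulk concentration), expected free
molecules per vesicle ((4π/3)r³·c·0.6022), and the vesicle turnover rate
needed to sustain a flux.

## Synthetic data

Generators are pure functions of (spec, seed) using
`numpy.random.default_rng`, and reduce exactly to their noiseless forward
models at σ = 0.

* **ACF curves**: forward model on a 200-point geometric lag grid from
  300 ns to 1 s (the correlator's point count and span; the exact
  multi-tau block structure is not reproduced), additive Gaussian noise,
  default σ = 0.005 on G.
* **Radial profiles**: sampled every 1 μm to 20 μm from the membrane, then
  every 10 μm to 100 μm.  The proximal peak is an exponential
  bulk·(1 + (fold−1)e^{−d/λ}) with fold = 3 and λ = 5 μm — the reported
  amplitude and extent; the exponential *shape* is a modelling choice, as
  no functional form was measured.  The distal peak is never drawn
  independently: it is the Fokker–Planck excess of the diffusivity dip
  over a window (default r ∈ [13, 35] μm) with the bulk level as both
  boundary values, so the concentration–diffusivity anticorrelation is
  structural.  A flat-diffusivity variant (no dip, no distal peak)
  emulates cells lacking the matrix-associated diffusion barrier;
  its concentration and diffusivity noise are independent, hence
  uncorrelated.  Noise is multiplicative log-normal, default σ = 0.05.
* **Titrations**: Hill∘power forward model with multiplicative log-normal
  noise (σ = 0.05); the identity mapping gives the vesicle-like control.
* **Lifetime decays**: multinomial photon-count histograms from a
  multi-exponential density, with a paired biexponential fitter
  (variance-stabilized least squares on expected counts) for recovery
  tests of the intensity-weighted lifetime.

The generators emulate the statistical *structure* of the measurements,
not their hardware artifacts: no detector afterpulsing, no correlator bias
at short lags, no membrane-fluctuation contributions to G(t), no spatial
correlation of noise between adjacent profile positions.  Recovery results
on synthetic data therefore demonstrate correctness of the estimators
under the stated noise models, not robustness to instrument systematics.

Noise magnitudes are plausible defaults, not measured facts: the source
experiments report error bars but not per-point noise models.

## Problem sizes

Default test and acceptance runs use the 400-cell grid, horizons of
2000–5000 s (long enough that the slowest scenario is within solver
tolerance of equilibrium), 100 seeds for FCS recovery studies and 50 for
profile/diffusivity studies — sizes chosen so each study gives stable
medians while the full suite stays interactive.

## Known limitations

* Spherical symmetry around an isolated cell; no adherent-monolayer or 3-D
  geometry.
* Receptors are immobile and conserved: no internalization, recycling, or
  receptor diffusion.
* Single-component ACF model only; no anomalous diffusion, membrane
  (2-D) components, or cross-correlation.
* The time-dependent Fokker–Planck problem (varying D plus kinetics) is
  not implemented; varying D is handled only at steady state.
* The default bulk→membrane mapping is a two-point reconstruction; with
  other calibration data the apparent-parameter magnitudes change (the
  direction of the distortion does not, for any concave mapping with
  enrichment near K_d).
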