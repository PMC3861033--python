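# Methods

## The model

A G1-arrested budding-yeast cell is idealized as a ball of radius
R = 3.95 µm.  Three polarity proteins exchange between the plasma
membrane (the sphere r = R) and the cytosol (the enclosed ball): the
GTPase Cdc42, its scaffold Bem1, and its GEF Cdc24.  Seven
concentration fields are tracked — on the membrane Cdc42-GTP (m_T),
Cdc42-GDP (m_D), free Bem1 (m_B) and the Bem1–Cdc24 complex (m_BG), in
µm⁻²; in the cytosol Cdc42-GDP (held by the GDI Rdi1, c_D), Bem1 (c_B)
and Cdc24 (c_G), in µm⁻³.

All chemistry is membrane-local mass action:

* nucleotide exchange m_D → m_T at rate α₂ + α₁·m_BG (intrinsic plus
  GEF-catalyzed);
* GAP-driven hydrolysis m_T → m_D at rate α₃;
* attachment of cytosolic Cdc42-GDP at the background rate β₂ (into
  m_D) and the GEF-mediated rate β₁·m_BG, which deposits Cdc42
  directly in GTP form (GEF displacement of the GDI plus immediate
  exchange);
* GDI extraction of membrane Cdc42-GDP at rate β₃ (the GTP form is not
  extracted);
* Bem1 recruitment at rate γ₁·m_T and detachment of free membrane Bem1
  at γ₂; Cdc24 binding to membrane Bem1 at δ₁·m_B and release of Cdc24
  from the complex at δ₂ (the complex releases Cdc24 only; Bem1 leaves
  the membrane solely via γ₂ acting on free m_B).

Membrane species diffuse laterally with D₂; cytosolic species diffuse
with D₃ and undergo no bulk reactions.  The two compartments couple
only through the boundary-flux conditions
−D₃ ∂_r c|_R = J (net attachment flux), so the three protein totals
N₄₂, N_B, N₂₄ are conserved exactly.  The positive feedback loop —
Cdc42-GTP recruits Bem1, Bem1 recruits Cdc24, membrane Cdc24 activates
and recruits more Cdc42 — is the pattern-forming mechanism; GDI
extraction supplies the fast recycling that lets the cap localize.

The control parameter set (units µm, s, molecules) is the calibrated
one: D₂ = 0.03, D₃ = 11, R = 3.95, N₄₂ = 3000, N_B = 6500, N₂₄ = 1000,
α₁ = 0.2, α₂ = 0.002 (printed as 0.12 min⁻¹), α₃ = 1, β₁ = 0.266,
β₂ = 0.28, β₃ = 1, γ₁ = 0.2667, γ₂ = 0.35, δ₁ = 0.00297, δ₂ = 0.35.

## Homogeneous state and linear stability

The unpolarized state is the uniform steady state reached by relaxing
the well-mixed two-compartment ODE system from the all-cytosolic
initial condition, polished by a Newton solve of the four membrane
balances plus the three conservation constraints (relative residual
< 1e−10).  This operational definition selects the stable unpolarized
branch when several roots exist.

Perturbations ∝ Y_l^m e^{σt} obey, per spherical-harmonic degree l
(rates are m-independent by isotropy, degeneracy 2l+1):

* each cytosolic amplitude solves the radial diffusion eigenproblem in
  the ball, regular at the origin — the modified spherical Bessel
  profile i_l(√(σ/D₃) r) for σ > 0, continued to j_l(√(−σ/D₃) r) for
  real σ < 0 and to r^l at σ = 0.  Only the logarithmic derivative
  q_l(σ) = φ′(R)/φ(R) enters; it is evaluated by scipy's spherical
  Bessel routines on the real axis and by a Lentz continued fraction
  for complex σ (both validated against each other and against the
  pure-diffusion closed form σ_l = −D₂ l(l+1)/R²);
* the four membrane amplitudes obey the linearized membrane equations
  (including −D₂ l(l+1)/R² lateral diffusion), and the three linearized
  boundary-flux conditions D₃ q_l(σ) ĉ_X = −δJ_X eliminate the
  cytosolic amplitudes, leaving a 4×4 σ-dependent matrix A(σ).

Growth rates are the self-consistent solutions of σ ∈ eig A(σ), found
by a dense scan of the real axis (with pole-aware sign-change
refinement) and a complex fixed-point fallback.  The l = 0 sector
contains the neutral total-mass mode (σ = 0).

**Two cytosol closures.**  `cytosol="full"` (default) is the exact
linearization above: a growing cap locally depletes the cytosol
beneath it, a negative feedback that lowers the leading rate.
`cytosol="reservoir"` treats the cytosol as a well-mixed reservoir
whose non-uniform perturbation vanishes (ĉ = 0, i.e. A is then
σ-independent).  At control parameters the full closure gives
σ₁ = 0.00367 s⁻¹ — confirmed to 0.01% by an independent linearized
radial-grid time integration, and to ~2.5% by the nonlinear solver at
its default step — while the reservoir closure gives σ₁ = 0.00415 s⁻¹,
matching the classic reported control-cell rate of 0.00417 s⁻¹ to
0.5%.  We therefore use the full closure wherever consistency with the
simulated dynamics matters (oracle tests, capability predicates) and
expose the reservoir closure for comparison with the reported linear
analysis; the ~12% gap between the two is a real, documented property
of the bulk–surface coupling at D₃ = 11 µm²/s, not a numerical error.

Polarization capability is Re σ_l > 0 for some 1 ≤ l ≤ l_max (default
l_max = 10, auto-extended until three consecutive degrees decay).

## Nonlinear solver

Membrane fields live on a Gauss–Legendre × uniform-longitude grid with
spherical-harmonic truncation L; the grid uses 3/2-rule padding
(nlat ≈ 3(L+1)/2, nlon ≈ 3(L+1)) so the quadratic reaction products
are projected without aliasing.  The cytosol is a physical grid of nr
uniform finite-volume radial cells under the same angular grid.
Default production resolution L = 32, nr = 24; the package's own
convergence check (final control cap width 3.629 µm at L = 16/nr = 16
vs 3.623 µm at L = 32/nr = 24, 0.15% apart) shows L = 16 is already
adequate for control-scale caps, so the test suite and sweep defaults
use L = 16–24 and the documented runs state their resolution.

Each time step Δt (default 0.5 s) is a Strang split A(Δt/2) B(Δt)
A(Δt/2), with adjacent half-steps fused:

* **A — tangential diffusion.**  Lateral membrane diffusion and the
  angular part of cytosolic diffusion are exact per-degree decay
  factors in spectral space.
* **B — radial diffusion + chemistry,** column-wise under each surface
  point.  A θ-scheme (θ = 0.55, slightly beyond trapezoidal to damp
  the stiffest radial modes) radial solve with the linearized
  attachment flux folded into the boundary row as a Robin condition
  predicts the membrane-contact concentrations; the contact value
  handed to the chemistry is centered at the step midpoint.  The
  membrane reactions are then integrated with substepped RK4 (substep
  count from a conservative local-rate bound) against those contact
  values.  Finally the columns are re-solved with the *realized*
  membrane uptake as a boundary source, so cytosol loss equals
  membrane gain identically.

Because the interior finite-volume operator telescopes and all
spectral filters leave the l = 0 mode untouched, the three totals are
conserved to round-off (observed drift ~1e−12 relative per run,
enforced at 1e−6 per 100 s).  Sharp caps can ring slightly negative on
the collocation grid; such values are clamped to zero and the affected
species field is rescaled to preserve its own integral
(clamp-and-renormalize, logged on the trajectory; worst observed
excursions are ~1e−3 of the local scale in strong-feedback sweeps).
The contact-concentration extrapolation from the outer cell center to
r = R uses the flux condition itself, making the attachment law
consistent to first order in the cell width.

Accuracy: the scheme is first order with a small constant in Δt for
the slow polarization mode; at Δt = 0.5 s the simulated l = 1 rate is
2.5% below the dispersion value, at Δt = 0.25 s 1.0% (the oracle tests
run at Δt = 0.25).  Deterministic given (initial state, options).

Steady state is declared when the maximum relative change of any
membrane field over 100 s falls below 1e−6 (control run converges near
t ≈ 3300 s); a state is "polarized" when the cluster height exceeds 5%
of the mean membrane Cdc42 density (configurable artifact threshold).

## Initial perturbations and synthetic data

* **Random lattice** — i.i.d. uniform[−1, 1] values on a cubic lattice
  of spacing 1 µm, interpolated trilinearly (bounded by 1, correlation
  length ~1 µm; the original interpolation scheme is unspecified, so
  trilinear is our documented choice), scaling every membrane species
  by (1 + 0.01 f(x)); the cytosol is untouched.  The multiplicative
  form means initial totals deviate from N by O(amplitude) — as in the
  original procedure — and conservation is checked against the
  *initial* totals.
* **Broad cap** — membrane species scaled by (1 + a·x̂·d/R), linear in
  one Cartesian coordinate and sign-changing at the cell center; the
  default amplitude 0.01 matches the random case (none is prescribed).
  The added term is odd, so totals are unchanged exactly.
* **Line scans** — a Gaussian cap of prescribed FWHM on a constant
  background along an equatorial contour of length 2πR, plus additive
  i.i.d. Gaussian noise.  Additive Gaussian noise stands in for the
  EMCCD noise law; the estimator tests sweep the noise amplitude
  instead of modelling the camera.  What these generators do *not*
  emulate: photobleaching, the point-spread function, z-projection,
  manual line-scan placement, or particle-number shot noise — so
  passing recovery tests demonstrate correctness of the estimation
  pipeline, not robustness to every imaging artifact.

## Cluster quantification

Background is the spatial median of the membrane density (configurable
to mean-of-lower-half); height is max − background.  FWHM is measured
along a great circle through the density maximum, with linear
interpolation at the half-height crossings — for multi-cap fields it
refers to the tallest cap.  Cluster counting thresholds the field
(smoothed by spectral truncation to degree 16) at background + 25% of
height and counts connected components with longitudinal wrap-around;
the threshold is an artifact choice and the suite checks insensitivity
across 0.1–0.5.  The microscopy-style route fits
base + A·exp(−(s−s₀)²/2σ²) to a line scan by nonlinear least squares
and reports 2√(2 ln 2)·σ; A ≤ 0, a flat trace or non-convergence yield
a "no cap" result.  The 3×3 blur uses a normalized σ = 0.85 px kernel
(the common 3×3 Gaussian discretization; only the kernel size is
prescribed) with reflective borders.

## Design choices and limitations

* The σ-scan bracket is [−10, 10] s⁻¹ with log-spaced refinement near
  zero; leading eigenvalues are real in the regimes studied, and
  imaginary parts are reported when the complex fallback engages.
* Simulation-backed FWHM sweeps reuse the previous polarized state as
  the next initial condition (continuation); cold-start cross-checks
  guard against hysteresis.
* In this model, *reducing* the extraction rate β₃ to one half or one
  third of control slightly *narrows* the final cap (3.44–3.53 µm vs
  3.63 µm at L = 16) while raising its height — the broadening
  expected from slow membrane turnover appears only at stronger
  reductions, and hydrolysis (α₃) reduction broadens monotonically
  (3.63 → 3.91 → 4.67 µm at 1×, 0.66×, 0.33×).  Cap positions, widths
  and counts are otherwise as expected: a single cap whose FWHM
  narrows monotonically after the nonlinear threshold.
* No moving or deforming geometry, no actin/vesicle delivery, no
  septin barrier, no stochastic particle-level dynamics, and no
  stability analysis of the *polarized* state.
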