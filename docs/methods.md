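# Model and methods

`pdlmech` implements an analytical continuum model of the periodontal
ligament (PDL): the thin, nearly incompressible soft-tissue layer anchoring
a tooth root in its bony socket. The root is a rigid elliptic paraboloid,
the PDL a layer of constant normal thickness bonded to the root on one side
and to the (rigid) alveolar bone on the other. Under an orthodontic-scale
load the root displaces quasi-statically and the ligament creeps; the model
resolves that creep with a fractional-order (Rabotnov) viscoelastic law and
maps the resulting strains and hydrostatic stresses over the root surface.

## Geometry

The root surface is `y/h = ((1-e^2) x^2 + z^2)/b^2` with height `h`, crest
minor semi-axis `b` and eccentricity `e` (major semi-axis
`a = b/sqrt(1-e^2)`). The surface is parameterised over the unit disc
(`x = a r cos(phi)`, `z = b r sin(phi)`), which maps the crest ellipse to
`r = 1` and keeps quadrature nodes off the apex, where the horizontal
direction cosines `H, G` of the normal are undefined. Surface integrals use
tensor Gauss–Legendre (radial) × trapezoid (angular, spectrally accurate
for periodic integrands) quadrature, 256×256 nodes by default; an optional
resolution-doubling check warns when an integral has not converged.

Two surface measures appear in the literature without definition: the true
area element `Delta dx dz` (with `Delta = sqrt(1 + |grad y|^2)`) and the
projected element `dx dz`. Both are implemented. The geometric identity
`∬ cos(alpha) dF = pi a b` (projection of the lateral surface onto the
crest plane) holds for the true element and is used as a quadrature
self-test.

The outer PDL surface is the normal offset of the root surface. The offset
of a paraboloid is not itself a paraboloid; the implemented shift map sends
outer-surface points one thickness along the (inward) normal onto the root
surface, which is the sense in which the offset-surface equation holds
exactly (verified by fixed-point construction in the tests).

## Kinematics and constitutive law

For a rigid root motion (translation `u0`, small rotations `theta`) the
ligament strains, in the local frame (normal `n`, generatrix tangent `t`,
circumferential tangent `theta`), are confined to the through-thickness
components:

    eps_nn = -(u·n)/delta,  gamma_nt = -(u·t)/delta,  gamma_ntheta = -(u·theta)/delta,

all in-surface strains vanishing — the incompressible-layer ansatz for a
thin ligament (Poisson ratio 0.49). The sign convention makes compression
of the ligament positive; it propagates into the stresses, so positive
hydrostatic stress denotes compression here. Engineering shears are used in
the local frame; the Cartesian tensor carries `gamma/2` off-diagonal. This
tensor-shear reading halves quoted shear magnitudes relative to an
engineering-shear reading and is the one under which the reported peak
shear lands near 0.48 (see "Reported, unasserted quantities").

The stress tensor follows a Rabotnov-type viscoelastic law: the elastic
isotropic law with every strain replaced by
`eps - nu_eps * conv(E_gamma(-t/tau_eps), eps)`, where

    E_gamma(-t/tau) = t^(gamma-1)/tau^gamma
                      sum_{n>=0} (-1)^n (t/tau)^(gamma n)/Gamma(gamma(n+1))

is the fractional-exponential relaxation kernel (the plain exponential at
`gamma = 1`), `nu_eps = (E_inf - E_0)/E_inf` in the sign convention of the
model (numerically positive, `E_0 > E_inf` being the instantaneous
modulus).

## Creep solution: two closed forms, deliberately

Integrating the traction over the root surface reduces the balance of
forces/moments to six Volterra equations coupled by a constant stiffness
matrix: `A L[q](t) = g(t)` with `L[u] = u - nu_eps conv(E_eps, u)`. Under a
constant load each mode creeps as `u(t) = (f/a) c(t)`.

The package ships **two** analytic creep factors, because the model's
traditional closed-form solution and the exact operator algebra disagree
by a unit shift in the Gamma arguments:

- `form="rabotnov"` (default):
  `c(t) = 1 + nu_sigma * sum_{m>=1} (-1)^(m-1) (t/tau_sigma)^(gamma m)/Gamma(gamma m)`
  `     = 1 + nu_sigma * t * E_gamma(-t/tau_sigma)`.
  This is the closed form from which the model's headline numbers follow
  (growth factors 1.75 at 10 s and 2.55 at 300 s relative to 1 s; ~9.5 N
  for full-thickness lateral compression). It is *not* an exact solution
  of the constitutive Volterra equation (residual O(1)), and it is not
  perfectly monotone: within the studied parameter ranges it can droop by
  up to ~0.5% late in the 300 s window.

- `form="mittag-leffler"`:
  `c(t) = 1 + nu_sigma * (1 - E_ML_gamma(-(t/tau_sigma)^gamma))`,
  the exact resolvent of `L` under the parameter conversion
  `nu_eps = nu_sigma/(1+nu_sigma)`, `tau_eps = tau_sigma (1-nu_eps)^(1/gamma)`
  (derived by Laplace transform; round-trip conversion is an identity).
  Substituted back into the constitutive equation it leaves a residual at
  numerical round-off (~1e-12, checked by regularized quadrature), and it
  is rigorously nondecreasing. It grows faster than the series form
  (ratios 1.99/4.4 instead of 1.75/2.55 for the reference kernel).

Headline quantities and defaults use the series form; solver validation and
the constitutive-residual property use the resolvent form. The prefactor of
the series form is implemented dimensionlessly as `(t/tau_sigma)^gamma`
(the literal `t^gamma/tau_sigma` is dimensionally inhomogeneous and is
available behind `prefactor="dimensional"` for comparison; it rescales the
transient by `tau_sigma^(gamma-1)` and cannot reproduce the growth
factors).

## Mittag-Leffler evaluation

`E_gamma(-y)` on the negative real axis is computed by Taylor series for
`y <= 1` and otherwise by the completely monotone spectral representation

    E_gamma(-t^gamma) = sin(gamma pi)/(gamma pi)
                        ∫_0^inf exp(-t v^(1/gamma)) / (v^2 + 2 v cos(gamma pi) + 1) dv,

integrated adaptively up to the point where the exponential factor reaches
e^-46 (for large arguments the whole mass sits in a narrow layer near
v = 0; a wider interval would dilute the quadrature). The `gamma = 1/2`
branch is cross-checked against `erfcx`, `gamma = 1` against the
exponential, and the series branch against 50-digit summation.

## Stiffness coefficients

The eight independent coefficients (`a11, a22, a33` translational,
`a44, a55, a66` rotational, `a16 = a61`, `a34 = a43` couplings) are surface
integrals of polynomial integrands scaled by
`A = E_inf/(2 delta b^2 (1+nu)(1-2nu))`. Three transcription ambiguities in
the published coefficient set were settled by regression against the
published coefficient table for the reference root, with the calibration
frozen as the package default and recorded in assembly metadata:

1. the **projected** element `dx dz` is the measure under which the table
   is reproduced (the true element misses by factors of ~2–5);
2. the `sin(alpha)` group in the `a11` integrand enters with a **plus**
   sign (as printed, with a minus, the integral is -5.009 MN/m against the
   tabulated +5.043 MN/m; the plus sign also restores the `a11 = a33`
   symmetry required at zero eccentricity);
3. the `a22` integrand carries a factor **2** (as printed it yields exactly
   half the tabulated value).

With these, all eight coefficients match the published values to better
than 0.06% at the default resolution, and coefficients change by <0.1% on
doubling it. `corrected=False` evaluates the literal forms. The centre of
resistance follows as `y1 = -a61/a11 ≈ 8.76 mm`, `y2 = a43/a33 ≈ 8.44 mm`
above the apex for the reference root.

## Volterra solver

`volterra_solve` integrates the coupled quasi-static system by product
integration: the solution is piecewise linear on a geometric time grid and
the kernel is integrated *exactly* over each cell via its Mittag-Leffler
primitive `E(s)` and the primitive's integral `P(s)` (both splined on a log
grid reaching far below `tau_eps`). This matters because the converted
relaxation time is tiny (~7e-7 s for the reference kernel): nearly the
entire kernel mass falls inside the final cell of every step, and any
scheme that samples the kernel rather than integrating it exactly fails at
O(1). Cell weights for the linear interpolant use the kernel mass and first
moment per cell; the step equation stays linear in the current state (one
LU solve of the 6×6 stiffness per step).

The default grid is geometric from 1e-6 s to 300 s with 600 nodes. The
early start is deliberate: the solution leaves `t = 0` like `t^gamma`, and
a first cell at 1e-2 s leaves a refinement-independent ~1e-3 relative error
plateau at late times; starting at 1e-6 s the solver tracks the closed-form
resolvent to ~1e-4 on [1, 300] s with observed convergence order ~1.5.
Inertia is dropped everywhere (see below); the solver's residual check
re-applies the same discretized operator and balances each equation to
~1e-13 of the load.

## Hydrostatic stress: exact vs quasi-elastic

Tracing the constitutive law, `sigma_h = E_inf/(3(1-2nu)) L[tr eps]`, and
`tr eps = -(u·n)/delta` for rigid motion. Under a constant load
`L[u] = f/a` is constant, so the *exact* viscoelastic hydrostatic stress is
time-invariant — relaxation exactly offsets creep, as it must for tractions
that keep balancing the same force (verified numerically to ~1e-5). The
growing stress maps the model is known for follow the *quasi-elastic*
reading: the elastic stress of the current (creeping) displacement, whose
surface maximum therefore grows exactly with the creep factor. Maps and
growth factors use the quasi-elastic route; `stress_tensor` provides the
full convolution route, and both are exercised in the tests.

For vertical translation the quasi-elastic closed form is
`sigma_h = -E_inf u0y cos(alpha)/(3 delta (1-2nu))`; the minus sign follows
from the kinematic convention above (the often-quoted variant without it is
available as `as_printed=True`). Its apex-to-crest ratio is the purely
geometric factor `Delta` at the crest — between 5.4 (major-axis meridian)
and 6.7 (minor-axis) for the reference root — and is time-invariant.

## Inertia

The root mass is 1e-3 kg (a desk value for a human tooth). The acceleration
of the creep solution is evaluated term-by-term from the series; it is
singular at `t = 0+` (`u ∝ t^gamma`), ~1.9e-5 m/s² at 1 s, and decays to
~1.9e-10 m/s² by 300 s for the reference 2 N intrusion. The quasi-static
approximation is justified not by the acceleration being uniformly tiny but
by the force comparison: `M |u''| / (a22 |u|) < 1e-8` throughout [1, 300] s.
Evaluation windows start at `t > 0`; the printed initial conditions
(vanishing first and second derivatives at 0) are not satisfied by a
`t^gamma` solution for `gamma < 1`.

## Parameters (reference preset, SI internally; config accepts mm/kPa)

| parameter | value | meaning |
|---|---|---|
| h | 13.0 mm | root height |
| b | 3.9 mm | crest minor semi-axis |
| e | 0.6 | crest eccentricity |
| delta | 0.229 mm | PDL thickness (normal) |
| E_inf | 680 kPa | relaxed modulus |
| nu | 0.49 | Poisson ratio (near-incompressible) |
| gamma | 0.35 | fractional parameter |
| tau_sigma | 550 s | retardation time |
| nu_sigma | 1.3e3 | creep amplitude, (E_0-E_inf)/E_inf inverse ratio |
| series tol / n_max | 1e-10 / 200 | kernel truncation control |

`truncation_order` reports the series order beyond which the creep factor
at a horizon changes by less than a tolerance; at 1e-3 over 300 s it gives
25/12/7 terms for `gamma = 0.25/0.5/0.75` (smaller `gamma`, slower
convergence). Loose visual-convergence counts of 20/10/3 sometimes quoted
for these exponents correspond to mutually inconsistent tolerances
(roughly 1e-2/3e-3/0.27 relative) and cannot be reproduced with a single
threshold.

## Reported, unasserted quantities

Two published figures are computed and reported but not enforced, because
they cannot follow from the implemented formulas: an apex-to-crest
hydrostatic-stress ratio of ~14 (the closed form bounds it by the geometric
factor ≤ 6.7, time-invariant) and a peak shear bound of 0.45 (the computed
tensor-shear maximum under the 2 N vertical load is 0.478, and the value is
convention-dependent).

## Limitations

Rigid root and socket; constant-thickness paraboloid ligament (no CBCT
geometries, no fibre anisotropy); linearized kinematics (rotations warn
above 0.1 rad); no contact/capping when the penetration approaches the full
thickness, so prescribed loads can formally exceed it; constant loads or
prescribed load programs only — no oscillatory mastication dynamics; no
bone-remodelling rate law (the hydrostatic field is the hand-off quantity).
The model is fully deterministic: identical configurations produce
bitwise-identical outputs, and the CLI's `--seed` flag is reserved but
inert.
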