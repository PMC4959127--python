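# pdlmech

Analytical mechanics of the periodontal ligament (PDL) — the thin,
nearly incompressible soft-tissue layer that suspends a tooth root in the
alveolar bone. `pdlmech` implements a fully analytical viscoelastic model
for orthodontic-scale loading: the root is a rigid elliptic paraboloid, the
ligament a bonded layer of constant normal thickness `δ`, and the tissue
response follows a fractional-order (Rabotnov) hereditary law. The package
is aimed at biomechanics researchers who want a fast, transparent
alternative to finite-element PDL models for initial tooth movement,
centre-of-resistance estimates and hydrostatic-stress (bone-remodelling
stimulus) mapping.

## The model in brief

* **Geometry** — root surface `y/h = ((1−e²)x² + z²)/b²`; the PDL occupies
  the normal offset layer of thickness `δ`.
* **Kinematics** — rigid root motion `(u₀, θ)`; ligament strains are
  confined across the thickness: `ε_nn = −(u·n)/δ`, `γ_nt = −(u·t)/δ`,
  `γ_nθ = −(u·θ)/δ` (compression positive).
* **Constitutive law** — isotropic elasticity with every strain replaced by
  `ε − ν_ε ∫₀ᵗ Ǝ_γ(−s/τ_ε) ε(t−s) ds`, where
  `Ǝ_γ(−t/τ) = (t^{γ−1}/τ^γ) Σₙ (−1)ⁿ (t/τ)^{γn}/Γ(γ(n+1))`
  is the fractional-exponential relaxation kernel (`γ = 1` gives the
  standard linear solid).
* **Equations of motion** — integrating tractions over the surface yields
  six Volterra equations coupled by a constant stiffness matrix with eight
  independent coefficients `a₁₁ … a₆₆, a₁₆ = a₆₁, a₃₄ = a₄₃`; inertia is
  negligible at 0–300 s time scales.
* **Creep** — under constant load each mode evolves as `u(t) = (f/a)·c(t)`;
  the package ships both the series closed form
  `c(t) = 1 + ν_σ Σₘ (−1)^{m−1}(t/τ_σ)^{γm}/Γ(γm)` (the model's headline
  form) and the exact Mittag-Leffler resolvent of the constitutive
  operator, plus a product-integration numerical solver for general load
  programs.
* **Stress** — hydrostatic stress `σ_h = tr σ / 3` mapped over the root
  surface; for vertical translation the quasi-elastic closed form is
  `σ_h = −E_∞ u₀y cos α / (3δ(1−2ν))`.

See `docs/methods.md` for assumptions, numerical choices and known
limitations (including the documented distinction between the series and
resolvent creep forms, and between exact viscoelastic and quasi-elastic
stress maps).

## Worked example

The built-in `reference` preset is a human-incisor-like root: `h = 13 mm`,
`b = 3.9 mm`, `e = 0.6`, `δ = 0.229 mm`, `E_∞ = 680 kPa`, `ν = 0.49`,
kernel `γ = 0.35`, `τ_σ = 550 s`, `ν_σ = 1.3·10³`.

```sh
$ pdlmech stiffness
a11 = 5.043 MN/m   a22 = 1.089 MN/m   a33 = 6.997 MN/m
a44 = 578.9 N m    a55 = 6.137 N m   a66 = 445.6 N m
a16 = a61 = -44.168 kN   a34 = a43 = 59.059 kN
centre of resistance: y1 = 8.76 mm, y2 = 8.44 mm
```

The diagonal entries are the translational (MN/m) and rotational (N·m)
stiffnesses of the root in its socket; the couplings place the centre of
resistance ~8.4–8.8 mm above the apex, the point a horizontal force must
pass through to translate the tooth without tipping.

```sh
$ pdlmech creep --axis y --force -2
u(0+) = -1.836e-06 m (elastic)   u(300 s) = -0.0002213 m   peak |eps_nn| = 0.966
```

A constant 2 N intrusive load displaces the root 1.8 µm instantly and
creeps to 0.22 mm — essentially the full ligament thickness — within
300 s (the displacement grows by ×1.75 between 1 s and 10 s and ×2.59 by
300 s). The peak normal strain 0.97 ≤ 1 is what the kernel parameters were
calibrated to.

```sh
$ pdlmech force-for --axis x --t 300
force along x for |u.n| = 0.000229 m at t = 300 s: 9.748 N
```

Pushing the ligament to full thickness sideways (at the crest meridian
point, where the surface normal is nearly horizontal) takes ~9.7 N because
the lateral stiffness `a11` is ~4.6× the vertical one.

```sh
$ pdlmech stress-map --axis x --force 2 --time 300
sigma_h range at t = 300 s: [-2.3253, 2.3253] MPa (16200 samples)
```

The horizontal-translation hydrostatic-stress map is antisymmetric:
compression on the side the root moves toward, tension opposite, zero along
the `x = 0` meridian (including the apex). `--out map.csv` exports
`x_mm, z_mm, y_mm, sigma_h_MPa` columns.

As a library:

```python
from pdlmech import (FractionalKernel, PDLMaterial, RootGeometry,
                     assemble_stiffness, creep_factor)

geom = RootGeometry(h=13e-3, b=3.9e-3, e=0.6, delta=0.229e-3)
S = assemble_stiffness(geom, PDLMaterial(e_inf=680e3, nu=0.49))
k = FractionalKernel(gamma=0.35, tau_sigma=550.0, nu_sigma=1.3e3)
u300 = -2.0 / S.a22 * creep_factor(300.0, k)   # -> -2.213e-4 m
```

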