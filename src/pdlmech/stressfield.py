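"""Viscoelastic stress tensor, hydrostatic stress and surface maps.

The constitutive law maps a strain history onto the stress tensor through
the Rabotnov relaxation kernel:

    sigma_ij(t) = E_inf / ((1 - 2 nu)(1 + nu)) * {
        (1 - 2 nu) (eps_ij - nu_eps conv(E_eps, eps_ij))
        + nu delta_ij (tr eps - nu_eps conv(E_eps, tr eps)) }

The hydrostatic stress ``sigma_h = tr(sigma)/3`` is the model's proxy for
the bone-remodelling stimulus.  Tracing the law gives

    sigma_h(t) = E_inf / (3 (1 - 2 nu)) * (tr eps - nu_eps conv(E_eps, tr eps)),

and since the rigid-motion strain trace is ``-(u . n)/delta``, the exact
viscoelastic ``sigma_h`` under a *constant* load is constant in time: the
relaxation convolution cancels the creep growth (the surface tractions
must keep balancing the same load).  The growing stress maps reported for
creeping roots instead follow the quasi-elastic reading -- the elastic
stress of the current displacement,

    sigma_h(t) = -E_inf (u(t) . n) / (3 delta (1 - 2 nu)),

which for vertical translation reduces to the closed form
``sigma_h = -E_inf u0y cos(alpha) / (3 delta (1 - 2 nu))``.  Both routes
are implemented; maps and growth factors use the quasi-elastic one, whose
spatial pattern is time-invariant and scales with the creep factor.

Sign convention: the kinematics measure ligament compression as positive
strain, so positive ``sigma_h`` denotes compression here.  The closed form
is often quoted without the kinematic minus sign (i.e. for the displacement
reckoned positive into the tissue); ``as_printed=True`` reproduces that
variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import RootGeometry, SurfaceQuadrature, local_frame
from .kinematics import RigidMotion, cartesian_strain_tensor
from .stiffness import PDLMaterial
from .viscokernel import FractionalKernel, convert_creep_relax, creep_factor

__all__ = [
    "StressState",
    "SurfaceField",
    "stress_tensor",
    "hydrostatic",
    "hydrostatic_vertical",
    "surface_map",
    "growth_factors",
]


@dataclass(frozen=True)
class StressState:
    """Symmetric stress tensor [Pa] and its hydrostatic part."""

    sigma: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.sigma, dtype=float)
        if s.shape != (3, 3) or not np.allclose(s, s.T, atol=1e-9 * max(1.0, np.abs(s).max())):
            raise ValueError("sigma must be a symmetric 3x3 tensor")
        object.__setattr__(self, "sigma", s)

    @property
    def sigma_h(self) -> float:
        return float(np.trace(self.sigma) / 3.0)


@dataclass
class SurfaceField:
    """Scalar field sampled on the root surface at one instant."""

    x: np.ndarray
    z: np.ndarray
    y: np.ndarray
    values: np.ndarray
    time: float
    name: str = "sigma_h"

    def __post_init__(self) -> None:
        if not (self.x.shape == self.z.shape == self.y.shape == self.values.shape):
            raise ValueError("coordinate and value arrays must share a shape")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")

    def to_dataframe(self):
        """Tidy frame with columns x[mm], z[mm], y[mm], <name>[MPa or unit]."""
        import pandas as pd

        return pd.DataFrame(
            {
                "x_mm": self.x.ravel() * 1e3,
                "z_mm": self.z.ravel() * 1e3,
                "y_mm": self.y.ravel() * 1e3,
                f"{self.name}_MPa": self.values.ravel() * 1e-6,
            }
        )


def _elastic_moduli(material: PDLMaterial) -> float:
    return material.e_inf / ((1 - 2 * material.nu) * (1 + material.nu))


def stress_tensor(
    t_grid: np.ndarray,
    eps_history: np.ndarray,
    kernel: FractionalKernel | None,
    material: PDLMaterial,
    t_eval: float,
) -> StressState:
    """Evaluate the constitutive law at ``t_eval`` for a sampled strain history.

    ``eps_history`` has shape ``(n_t, 3, 3)`` on the increasing grid
    ``t_grid`` (starting at 0), which must cover ``t_eval``.  With
    ``kernel=None`` the elastic limit (no relaxation convolution) is
    evaluated at the strain interpolated to ``t_eval``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    eps_history = np.asarray(eps_history, dtype=float)
    if eps_history.shape != (t_grid.size, 3, 3):
        raise ValueError("eps_history must have shape (n_t, 3, 3)")
    if t_eval < t_grid[0] or t_eval > t_grid[-1] + 1e-12 * max(t_eval, 1.0):
        raise ValueError("t_eval outside the sampled strain history")

    def interp_eps(tt: float) -> np.ndarray:
        out = np.empty((3, 3))
        for i in range(3):
            for j in range(3):
                out[i, j] = np.interp(tt, t_grid, eps_history[:, i, j])
        return out

    eps_t = interp_eps(t_eval)
    if kernel is None:
        eff = eps_t
    else:
        kernel = convert_creep_relax(kernel)
        from .motion import _ProductIntegrator

        # restrict the history to [0, t_eval]; product integration against
        # the kernel primitive handles the short relaxation time exactly
        mask = t_grid < t_eval
        t_sub = np.concatenate([t_grid[mask], [t_eval]])
        eps_sub = np.concatenate([eps_history[mask], eps_t[None]], axis=0)
        integ = _ProductIntegrator(kernel, s_max=max(t_eval, kernel.tau_eps))
        if t_eval > 0:
            w = integ.node_weights(t_sub, t_sub.size - 1)
            conv = np.tensordot(w, eps_sub, axes=(0, 0))
        else:
            conv = np.zeros((3, 3))
        eff = eps_t - kernel.nu_eps * conv
    n2 = 1 - 2 * material.nu
    sigma = _elastic_moduli(material) * (n2 * eff + material.nu * np.trace(eff) * np.eye(3))
    return StressState(sigma=sigma)


def hydrostatic(state: StressState) -> float:
    """Mean direct stress ``(sigma_xx + sigma_yy + sigma_zz) / 3`` [Pa]."""
    return state.sigma_h


def hydrostatic_vertical(
    x: float,
    z: float,
    u0y: float,
    geom: RootGeometry,
    material: PDLMaterial,
    as_printed: bool = False,
) -> float:
    """Closed-form quasi-elastic hydrostatic stress under vertical translation.

    ``sigma_h = -E_inf u0y cos(alpha) / (3 delta (1 - 2 nu))`` with
    ``cos(alpha) = n_y`` at the point; proportional to ``u0y(t)``, so the
    spatial pattern is time-invariant up to scale.  ``as_printed=True``
    drops the kinematic minus sign (displacement reckoned positive into the
    tissue).
    """
    cos_a = local_frame(x, z, geom).cos_alpha
    val = material.e_inf * u0y * cos_a / (3 * geom.delta * (1 - 2 * material.nu))
    return val if as_printed else -val


def surface_map(
    u0: np.ndarray,
    geom: RootGeometry,
    material: PDLMaterial,
    time: float = 0.0,
    n_r: int = 90,
    n_phi: int = 180,
) -> SurfaceField:
    """Quasi-elastic hydrostatic-stress map for a rigid translation ``u0`` [m].

    The strain trace at each surface point is ``-(u0 . n)/delta``; the map
    is sampled on an ``(n_r, n_phi)`` grid (apex excluded as in the
    quadrature).  For a horizontal translation the map is antisymmetric
    under ``x -> -x`` and vanishes on the meridian ``x = 0`` including the
    apex; compression (positive values) develops on the side the root moves
    towards.
    """
    u0 = np.asarray(u0, dtype=float)
    quad = SurfaceQuadrature(geom, n_r=n_r, n_phi=n_phi)
    b2 = geom.b**2
    nx = -2 * (1 - geom.e**2) * geom.h * quad.x / (b2 * quad.Delta)
    ny = 1.0 / quad.Delta
    nz = -2 * geom.h * quad.z / (b2 * quad.Delta)
    u_dot_n = u0[0] * nx + u0[1] * ny + u0[2] * nz
    trace = -u_dot_n / geom.delta
    sig_h = material.e_inf * trace / (3 * (1 - 2 * material.nu))
    return SurfaceField(x=quad.x, z=quad.z, y=quad.y, values=sig_h, time=time)


def growth_factors(
    times,
    u_per_unit: np.ndarray,
    geom: RootGeometry,
    material: PDLMaterial,
    kernel: FractionalKernel,
    t_ref: float = 1.0,
    form: str = "rabotnov",
) -> np.ndarray:
    """Ratios of the surface maximum of ``|sigma_h|`` at ``times`` to its
    value at ``t_ref`` for a constant-load translation.

    ``u_per_unit`` is the elastic translation direction/magnitude (the
    ``t = 0`` response); each map is the quasi-elastic stress of
    ``u_per_unit * c(t)``.  By linearity the ratios equal the creep-factor
    ratios; they are nevertheless measured from the sampled maps.
    """
    times = np.asarray(times, dtype=float)
    ref_map = surface_map(
        np.asarray(u_per_unit) * float(creep_factor(t_ref, kernel, form=form)),
        geom,
        material,
        time=t_ref,
    )
    ref = np.abs(ref_map.values).max()
    out = np.empty(times.size)
    for i, tt in enumerate(times):
        m = surface_map(
            np.asarray(u_per_unit) * float(creep_factor(tt, kernel, form=form)),
            geom,
            material,
            time=tt,
        )
        out[i] = np.abs(m.values).max() / ref
    return out
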