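"""Rigid-root displacement field and PDL strains in the surface frame.

The root is rigid and perfectly bonded to the inner PDL surface, while the
outer PDL surface is fixed to the alveolar bone.  For a nearly
incompressible ligament the tissue accommodates root motion by straining
across its (thin) thickness only: at each surface point the nonzero strain
components in the local frame ``(n, t, theta)`` are

    eps_nn    = -u_n / delta        (normal strain)
    gamma_nt  = -u_t / delta        (engineering shear, normal-generatrix)
    gamma_nth = -u_th / delta       (engineering shear, normal-circumferential)

with ``u`` the rigid-body displacement of the root surface point.  Sign
convention: compression of the ligament by root motion towards the socket
wall gives positive ``eps_nn``.  Engineering
shears are twice the tensor shears; the Cartesian tensor therefore carries
``gamma/2`` off-diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import RootGeometry, local_frame

__all__ = [
    "RigidMotion",
    "StrainComponents",
    "rigid_displacement",
    "strain_components",
    "cartesian_strain_tensor",
]

_ROTATION_WARN = 0.1  # rad; linearized kinematics degrade above this


@dataclass(frozen=True)
class RigidMotion:
    """Small rigid-body motion: translation ``u0`` [m] and rotation ``theta`` [rad]."""

    u0: np.ndarray
    theta: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "u0", np.asarray(self.u0, dtype=float))
        object.__setattr__(self, "theta", np.asarray(self.theta, dtype=float))
        if self.u0.shape != (3,) or self.theta.shape != (3,):
            raise ValueError("u0 and theta must be 3-vectors")
        if np.any(np.abs(self.theta) > _ROTATION_WARN):
            import warnings

            warnings.warn(
                "rotation angles exceed 0.1 rad; linearized kinematics unreliable",
                stacklevel=2,
            )


@dataclass(frozen=True)
class StrainComponents:
    """PDL strain components in the local frame; in-surface strains vanish."""

    eps_nn: float
    gamma_nt: float
    gamma_ntheta: float
    eps_tt: float = 0.0
    eps_thth: float = 0.0
    gamma_ttheta: float = 0.0


def rigid_displacement(point, motion: RigidMotion) -> np.ndarray:
    """Linearized rigid-body displacement ``u0 + theta x r`` at ``point``.

    Componentwise: ``u_x = u0x + z th_y - y th_z``,
    ``u_y = u0y - z th_x + x th_z``, ``u_z = u0z + y th_x - x th_y``.
    """
    point = np.asarray(point, dtype=float)
    return motion.u0 + np.cross(motion.theta, point)


def strain_components(
    x: float, z: float, motion: RigidMotion, geom: RootGeometry
) -> StrainComponents:
    """Local-frame PDL strains produced by a rigid root motion at ``(x, z)``."""
    from .geometry import elevation

    y = float(elevation(x, z, geom))
    frame = local_frame(x, z, geom)
    u = rigid_displacement([x, y, z], motion)
    d = geom.delta
    return StrainComponents(
        eps_nn=-float(u @ frame.n) / d,
        gamma_nt=-float(u @ frame.t) / d,
        gamma_ntheta=-float(u @ frame.theta) / d,
    )


def cartesian_strain_tensor(
    x: float, z: float, motion: RigidMotion, geom: RootGeometry
) -> np.ndarray:
    """Strain tensor in global axes (tensor shears, i.e. ``gamma/2`` off-diagonal).

    The local-frame strain matrix is rotated into the global frame with the
    orthogonal matrix whose rows are ``(n, t, theta)``; rotating back
    recovers the local components exactly.
    """
    s = strain_components(x, z, motion, geom)
    frame = local_frame(x, z, geom)
    local = np.array(
        [
            [s.eps_nn, s.gamma_nt / 2.0, s.gamma_ntheta / 2.0],
            [s.gamma_nt / 2.0, 0.0, 0.0],
            [s.gamma_ntheta / 2.0, 0.0, 0.0],
        ]
    )
    R = np.vstack([frame.n, frame.t, frame.theta])  # rows: local axes in global coords
    return R.T @ local @ R
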