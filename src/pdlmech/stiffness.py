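"""Stiffness coefficients of the rigid-root equations of motion.

Integrating the elastic part of the constitutive law over the root surface
turns the quasi-static balance of forces and moments into a linear system
in the six rigid-body unknowns ``(u0x, u0y, u0z, th_x, th_y, th_z)`` with
eight independent coefficients: diagonal translational stiffnesses
``a11, a22, a33`` [N/m], rotational stiffnesses ``a44, a55, a66`` [N m] and
the translation-rotation couplings ``a16 = a61`` and ``a34 = a43`` [N].
Each coefficient is a surface integral of a polynomial in the point
coordinates and the direction cosines ``cos(alpha) = n_y``,
``sin(alpha)``, ``H`` and ``G``, scaled by the common factor

    A = E_inf / (2 delta b^2 (1 + nu) (1 - 2 nu)).

Two transcription corrections are applied by default (``corrected=True``):
the sign of the ``sin(alpha)`` group in the ``a11`` integrand and a factor
2 on the ``a22`` integrand.  Both are fixed by regression against the
published coefficient table for the reference geometry (the literal forms
give ``a11`` with the wrong sign and ``a22`` at exactly half the tabulated
value) and by the requirement that ``a11 = a33`` when the crest ellipse
degenerates to a circle (``e = 0``).  ``corrected=False`` evaluates the
literal forms.  The surface element is the projected one (``dx dz``) by
default, which the same regression selects over the true area element; see
``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import RootGeometry, SurfaceQuadrature

__all__ = [
    "PDLMaterial",
    "StiffnessMatrix",
    "COEFFICIENT_NAMES",
    "appendix_integrand",
    "assemble_stiffness",
    "center_of_resistance",
]

COEFFICIENT_NAMES = ("a11", "a16", "a22", "a33", "a34", "a44", "a55", "a66")


@dataclass(frozen=True)
class PDLMaterial:
    """Elastic constants of the ligament: relaxed modulus [Pa], Poisson ratio."""

    e_inf: float
    nu: float

    def __post_init__(self) -> None:
        if not self.e_inf > 0:
            raise ValueError(f"relaxed modulus must be positive, got {self.e_inf}")
        if not 0 < self.nu < 0.5:
            raise ValueError(f"Poisson ratio must be in (0, 0.5), got {self.nu}")

    def amplitude(self, geom: RootGeometry) -> float:
        """Common prefactor ``A = E_inf / (2 delta b^2 (1+nu)(1-2nu))``."""
        return self.e_inf / (2 * geom.delta * geom.b**2 * (1 + self.nu) * (1 - 2 * self.nu))


@dataclass(frozen=True)
class StiffnessMatrix:
    """The eight independent stiffness coefficients plus assembly metadata.

    ``a16 == a61`` and ``a34 == a43`` by construction (one integral each).
    """

    a11: float
    a22: float
    a33: float
    a44: float
    a55: float
    a66: float
    a16: float
    a34: float
    metadata: dict = field(default_factory=dict)

    @property
    def a61(self) -> float:
        return self.a16

    @property
    def a43(self) -> float:
        return self.a34

    def system_matrix(self) -> np.ndarray:
        """Full 6x6 matrix in the unknown order (u0x, u0y, u0z, th_x, th_y, th_z)."""
        M = np.zeros((6, 6))
        M[0, 0], M[0, 5] = self.a11, self.a16
        M[1, 1] = self.a22
        M[2, 2], M[2, 3] = self.a33, self.a34
        M[3, 2], M[3, 3] = self.a43, self.a44
        M[4, 4] = self.a55
        M[5, 0], M[5, 5] = self.a61, self.a66
        return M

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in COEFFICIENT_NAMES}


def _integrand_fields(quad: SurfaceQuadrature, geom: RootGeometry, material: PDLMaterial):
    x, z, y = quad.x, quad.z, quad.y
    c, s = quad.cos_alpha, quad.sin_alpha
    H, G = quad.H, quad.G
    b2 = geom.b**2
    h = geom.h
    e2 = geom.e**2
    n1 = 1.0 - material.nu  # (1 - nu)
    n2 = 1.0 - 2.0 * material.nu  # (1 - 2 nu)
    Hx = H * x * (1 - e2)
    Gz = G * z
    return x, z, y, c, s, H, G, b2, h, e2, n1, n2, Hx, Gz


def appendix_integrand(
    name: str,
    quad: SurfaceQuadrature,
    geom: RootGeometry,
    material: PDLMaterial,
    corrected: bool = True,
) -> np.ndarray:
    """Node values of the (unscaled-by-A) integrand for one coefficient.

    ``name`` is one of :data:`COEFFICIENT_NAMES`.  With ``corrected=False``
    the literal transcription is evaluated (``a11`` with a minus on the
    ``sin(alpha)`` group, ``a22`` without the factor 2).
    """
    if name not in COEFFICIENT_NAMES:
        raise ValueError(f"unknown stiffness coefficient {name!r}")
    x, z, y, c, s, H, G, b2, h, e2, n1, n2, Hx, Gz = _integrand_fields(quad, geom, material)

    if name == "a11":
        sign = 1.0 if corrected else -1.0
        return b2 * n2 * c + sign * 2 * h * (2 * Hx * n1 + Gz * n2) * s
    if name == "a16":
        return -(
            (4 * (1 - e2) * h * material.nu * x**2 + b2 * y * n2) * c
            + (b2 * H * x * n2 + 2 * h * y * (2 * Hx * n1 + Gz * n2)) * s
        )
    if name == "a22":
        factor = 2.0 if corrected else 1.0
        return factor * (b2 * n1 * c + h * n2 * (Hx + Gz) * s)
    if name == "a33":
        return b2 * n2 * c + 2 * h * (Hx * n2 + 2 * Gz * n1) * s
    if name == "a34":
        return (b2 * y * n2 + 4 * h * material.nu * z**2) * c + (
            2 * Hx * h * y * n2 + Gz * (b2 * n2 + 4 * h * y * n1)
        ) * s
    if name == "a44":
        return (2 * h * y * z**2 + b2 * (n2 * y**2 + 2 * n1 * z**2)) * c + (
            2 * h * Hx * n2 * (y**2 + z**2) + Gz * (b2 * y + 2 * h * (2 * y**2 * n1 + n2 * z**2))
        ) * s
    if name == "a55":
        r2 = x**2 + z**2
        return b2 * n2 * r2 * c + (
            2
            * h
            * (
                Gz * (e2 * x**2 + n2 * r2)
                + H * x * (r2 * n2 - e2 * (n2 * x**2 + 2 * n1 * z**2))
            )
        ) * s
    # a66
    return (2 * h * x**2 * y * (1 - e2) + b2 * (2 * n1 * x**2 + n2 * y**2)) * c + (
        b2 * H * x * y + 2 * h * (Hx * (n2 * x**2 + 2 * n1 * y**2) + G * n2 * (x**2 + y**2) * z)
    ) * s


def assemble_stiffness(
    geom: RootGeometry,
    material: PDLMaterial,
    n_r: int = 256,
    n_phi: int = 256,
    element: str = "projected",
    corrected: bool = True,
) -> StiffnessMatrix:
    """Assemble all eight coefficients by surface quadrature.

    ``element`` selects the surface measure: ``"projected"`` (``dx dz``,
    the calibrated default) or ``"true"`` (``Delta dx dz``).
    """
    quad = SurfaceQuadrature(geom, n_r=n_r, n_phi=n_phi)
    A = material.amplitude(geom)
    vals = {
        name: A * quad.integrate(appendix_integrand(name, quad, geom, material, corrected), element)
        for name in COEFFICIENT_NAMES
    }
    meta = {
        "element": element,
        "corrected": corrected,
        "n_r": n_r,
        "n_phi": n_phi,
        "geometry": {"h": geom.h, "b": geom.b, "e": geom.e, "delta": geom.delta},
        "material": {"e_inf": material.e_inf, "nu": material.nu},
    }
    return StiffnessMatrix(
        a11=vals["a11"],
        a22=vals["a22"],
        a33=vals["a33"],
        a44=vals["a44"],
        a55=vals["a55"],
        a66=vals["a66"],
        a16=vals["a16"],
        a34=vals["a34"],
        metadata=meta,
    )


def center_of_resistance(S: StiffnessMatrix) -> tuple[float, float]:
    """Heights ``(y1, y2)`` [m] of the centre of resistance on the root axis.

    A horizontal force along ``x`` applied at ``(0, y1, 0)`` (resp. along
    ``z`` at ``(0, y2, 0)``) produces pure translation: the moment equation
    is then satisfied identically, giving ``y1 = -a61/a11`` and
    ``y2 = a43/a33``.
    """
    if S.a11 == 0 or S.a33 == 0:
        raise ZeroDivisionError("diagonal stiffness vanishes")
    return -S.a61 / S.a11, S.a43 / S.a33
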