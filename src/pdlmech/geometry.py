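"""Elliptic-paraboloid root surface, PDL offset surface, local frames, quadrature.

The tooth root is modelled as a rigid elliptic paraboloid

    F(x, y, z) = y/h - ((1 - e^2) x^2 + z^2) / b^2 = 0,

where ``h`` is the root height, ``b`` the minor semi-axis of the crest
ellipse at ``y = h`` and ``e`` its eccentricity (major semi-axis
``a = b / sqrt(1 - e^2)``).  The periodontal ligament (PDL) is the layer of
constant thickness ``delta`` between this surface and its normal offset.

All quantities are SI (metres); configuration-level unit conversion lives in
:mod:`pdlmech.config`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss

__all__ = [
    "RootGeometry",
    "LocalFrame",
    "SurfaceQuadrature",
    "elevation",
    "unit_normal",
    "local_frame",
    "offset_point",
    "surface_integrate",
]


@dataclass(frozen=True)
class RootGeometry:
    """Paraboloid root shape and PDL thickness.

    Parameters
    ----------
    h : float
        Root height [m].
    b : float
        Minor semi-axis of the crest ellipse [m].
    e : float
        Eccentricity of the crest ellipse, ``0 <= e < 1``.
    delta : float
        PDL thickness along the surface normal [m].
    """

    h: float
    b: float
    e: float
    delta: float

    def __post_init__(self) -> None:
        if not self.h > 0:
            raise ValueError(f"root height h must be positive, got {self.h}")
        if not self.b > 0:
            raise ValueError(f"semi-axis b must be positive, got {self.b}")
        if not 0 <= self.e < 1:
            raise ValueError(f"eccentricity e must be in [0, 1), got {self.e}")
        if not self.delta > 0:
            raise ValueError(f"PDL thickness delta must be positive, got {self.delta}")

    @property
    def a(self) -> float:
        """Major semi-axis of the crest ellipse [m]."""
        return self.b / np.sqrt(1.0 - self.e**2)

    def Delta(self, x, z):
        """Normalisation factor of the surface gradient, ``Delta >= 1``.

        ``Delta = sqrt(b^4 + 4 h^2 ((1-e^2)^2 x^2 + z^2)) / b^2``; the unit
        normal has vertical component ``n_y = 1/Delta`` and the true area
        element of the surface is ``Delta dx dz``.
        """
        x = np.asarray(x, dtype=float)
        z = np.asarray(z, dtype=float)
        b2 = self.b**2
        return np.sqrt(b2**2 + 4 * self.h**2 * ((1 - self.e**2) ** 2 * x**2 + z**2)) / b2


@dataclass(frozen=True)
class LocalFrame:
    """Orthonormal surface frame (normal, generatrix tangent, circumferential).

    ``n`` is the unit surface normal with ``n_y > 0``; ``t`` is the unit
    tangent along the generatrix (in the meridian plane through the point,
    ``t_y = sin_alpha``); ``theta = n x t`` is the horizontal circumferential
    tangent.  ``cos_alpha = n_y`` is the cosine of the angle between the
    normal and the vertical axis, and ``(H, G)`` are the direction cosines of
    the horizontal projection of the radial direction, so that
    ``n_x = -H sin_alpha`` and ``n_z = -G sin_alpha``.
    """

    n: np.ndarray
    t: np.ndarray
    theta: np.ndarray
    cos_alpha: float
    sin_alpha: float
    H: float
    G: float


def elevation(x, z, geom: RootGeometry):
    """Height ``y`` of the root surface above the horizontal point ``(x, z)``.

    Raises
    ------
    ValueError
        If the point projects outside the crest ellipse
        ``(1-e^2) x^2 + z^2 > b^2``.
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    r2 = (1 - geom.e**2) * x**2 + z**2
    if np.any(r2 > geom.b**2 * (1 + 1e-12)):
        raise ValueError("point projects outside the crest ellipse")
    return geom.h * r2 / geom.b**2


def unit_normal(x, z, geom: RootGeometry):
    """Unit normal to the root surface, oriented with ``n_y > 0``.

    At the apex (``x = z = 0``) the normal is the vertical axis.
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    D = geom.Delta(x, z)
    b2 = geom.b**2
    nx = -2 * (1 - geom.e**2) * geom.h * x / (b2 * D)
    ny = 1.0 / D
    nz = -2 * geom.h * z / (b2 * D)
    return np.stack(np.broadcast_arrays(nx, ny, nz), axis=-1)


def _HG(x: float, z: float, geom: RootGeometry) -> tuple[float, float]:
    rho = np.hypot((1 - geom.e**2) * x, z)
    if rho == 0.0:
        # apex convention: radial direction along +x
        return 1.0, 0.0
    return (1 - geom.e**2) * x / rho, z / rho


def local_frame(x: float, z: float, geom: RootGeometry) -> LocalFrame:
    """Orthonormal right-handed frame ``(n, t, theta)`` at a surface point.

    At the apex the horizontal direction cosines are undefined; by
    convention the frame there aligns ``t`` with ``+x`` and ``theta`` with
    ``-z`` (the continuous limit along the ``z = 0`` meridian).
    """
    H, G = _HG(x, z, geom)
    D = float(geom.Delta(x, z))
    cos_a = 1.0 / D
    sin_a = float(np.sqrt(max(0.0, 1.0 - cos_a**2)))
    n = np.array([-H * sin_a, cos_a, -G * sin_a])
    t = np.array([H * cos_a, sin_a, G * cos_a])
    theta = np.array([G, 0.0, -H])
    return LocalFrame(n=n, t=t, theta=theta, cos_alpha=cos_a, sin_alpha=sin_a, H=H, G=G)


def offset_point(x: float, z: float, geom: RootGeometry) -> np.ndarray:
    """Normal shift ``(x + n_x delta, y + n_y delta, z + n_z delta)`` of a
    surface point.

    This is the shift map appearing in the offset-surface equation
    ``F1 = 0``: a point lies on the outer PDL surface exactly when its
    shifted image lies on the root paraboloid (the normal points into the
    root, so outer-surface points map onto the root surface).  Applied at a
    root-surface point, as here, it returns the point one PDL thickness
    into the root along the normal; at the apex that is ``(0, delta, 0)``.
    """
    y = float(elevation(x, z, geom))
    n = unit_normal(x, z, geom)
    return np.array([x, y, z]) + geom.delta * np.asarray(n, dtype=float)


@dataclass
class SurfaceQuadrature:
    """Tensor quadrature over the lateral root surface ``0 <= y <= h``.

    The surface is parameterised over the unit disc,
    ``x = a r cos(phi)``, ``z = b r sin(phi)``, ``r in (0, 1]``, with
    Gauss-Legendre nodes in ``r`` and an equispaced (trapezoid, spectrally
    accurate for periodic integrands) rule in ``phi``.  The apex ``r = 0``
    carries no quadrature node, so fields whose horizontal direction cosines
    are undefined there remain integrable.

    Attributes ``x, z, y, rho, Delta, cos_alpha, sin_alpha, H, G`` are
    ``(n_r, n_phi)`` node arrays; ``w_proj`` is the weight of the projected
    element ``dx dz`` and ``w_true = Delta * w_proj`` that of the true area
    element.
    """

    geom: RootGeometry
    n_r: int = 256
    n_phi: int = 256

    def __post_init__(self) -> None:
        g = self.geom
        xg, wg = leggauss(self.n_r)
        r = 0.5 * (xg + 1.0)
        wr = 0.5 * wg
        phi = 2 * np.pi * np.arange(self.n_phi) / self.n_phi
        wphi = 2 * np.pi / self.n_phi
        R, PHI = np.meshgrid(r, phi, indexing="ij")
        a = g.a
        self.r = R
        self.phi = PHI
        self.x = a * R * np.cos(PHI)
        self.z = g.b * R * np.sin(PHI)
        self.y = g.h * ((1 - g.e**2) * self.x**2 + self.z**2) / g.b**2
        self.rho = np.hypot((1 - g.e**2) * self.x, self.z)
        self.Delta = g.Delta(self.x, self.z)
        self.cos_alpha = 1.0 / self.Delta
        self.sin_alpha = 2 * g.h * self.rho / (g.b**2 * self.Delta)
        self.H = (1 - g.e**2) * self.x / self.rho
        self.G = self.z / self.rho
        # dx dz = a b r dr dphi
        self.w_proj = a * g.b * R * np.outer(wr, np.full(self.n_phi, wphi))
        self.w_true = self.Delta * self.w_proj

    def weights(self, element: str = "true") -> np.ndarray:
        if element == "true":
            return self.w_true
        if element == "projected":
            return self.w_proj
        raise ValueError(f"unknown surface element convention: {element!r}")

    def integrate(self, values, element: str = "true") -> float:
        """Integrate a node-sampled (or callable ``f(x, z)``) scalar field."""
        if callable(values):
            values = values(self.x, self.z)
        return float(np.sum(np.asarray(values) * self.weights(element)))


def surface_integrate(
    f,
    geom: RootGeometry,
    n_r: int = 256,
    n_phi: int = 256,
    element: str = "true",
    check: bool = False,
    rtol: float = 1e-6,
) -> float:
    """Surface integral of ``f(x, z)`` over the lateral paraboloid surface.

    With ``check=True`` the resolution is doubled once and a warning is
    emitted if the two estimates differ by more than ``rtol`` relatively
    (the finer estimate is returned either way).
    """
    quad = SurfaceQuadrature(geom, n_r=n_r, n_phi=n_phi)
    val = quad.integrate(f, element=element)
    if check:
        fine = SurfaceQuadrature(geom, n_r=2 * n_r, n_phi=2 * n_phi).integrate(f, element=element)
        scale = max(abs(val), abs(fine), 1e-300)
        if abs(fine - val) > rtol * scale:
            warnings.warn(
                f"surface integral changed by {abs(fine - val) / scale:.2e} "
                f"on doubling the quadrature resolution (rtol={rtol:g})",
                stacklevel=2,
            )
        return fine
    return val
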