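"""Quasi-static motion of the rigid root in the viscoelastic ligament.

The balance of forces and moments on the root yields a system of six
Volterra integral equations of the second kind: every rigid-body unknown
``q_i`` enters through the same scalar relaxation operator

    L[q](t) = q(t) - nu_eps * int_0^t E_gamma(-s/tau_eps) q(t - s) ds,

coupled by the constant stiffness matrix ``a_ij``:  ``A L[q](t) = g(t)``
with ``g`` the load vector ``(f_x, f_y, f_z, y_f f_z - z_f f_y,
z_f f_x - x_f f_z, x_f f_y - y_f f_x)``.  Inertia is negligible at
orthodontic time scales (see :func:`inertia_estimate`) and is dropped from
all solvers.

Closed-form constant-load solutions use the creep factor
``u(t) = (f/a) c(t)`` of :func:`pdlmech.viscokernel.creep_factor`; the
general solver :func:`volterra_solve` discretizes the convolution by
product integration with exact Mittag-Leffler weights, which handles both
the weak ``t^(gamma-1)`` singularity of the kernel and the extremely short
relaxation time ``tau_eps`` implied by a nearly incompressible ligament.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.special import gamma as _gamma

from .geometry import RootGeometry, SurfaceQuadrature
from .stiffness import StiffnessMatrix, center_of_resistance
from .viscokernel import (
    FractionalKernel,
    convert_creep_relax,
    creep_factor,
    mittag_leffler_neg,
)

__all__ = [
    "LoadCase",
    "InertiaProps",
    "DisplacementHistory",
    "default_time_grid",
    "vertical_creep",
    "horizontal_creep",
    "required_force",
    "volterra_solve",
    "volterra_residual",
    "inertia_estimate",
]

#: Root mass [kg] used for inertia assessments.
ROOT_MASS = 1e-3


@dataclass(frozen=True)
class LoadCase:
    """Concentrated load: force vector [N], application point [m], extra moment [N m]."""

    f: np.ndarray
    r_f: np.ndarray
    m_ext: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        for name in ("f", "r_f", "m_ext"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be a finite 3-vector")
            object.__setattr__(self, name, v)

    def generalized(self) -> np.ndarray:
        """Six-component load vector (forces, then load-point moments)."""
        m = np.cross(self.r_f, self.f) + self.m_ext
        return np.concatenate([self.f, m])


@dataclass(frozen=True)
class InertiaProps:
    """Mass [kg] and axial moments of inertia [kg m^2] of the root."""

    M: float = ROOT_MASS
    J: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if not self.M > 0:
            raise ValueError("mass must be positive")
        J = np.asarray(self.J, dtype=float)
        if J.shape != (3,) or np.any(J < 0):
            raise ValueError("J must be three nonnegative moments")
        object.__setattr__(self, "J", J)


@dataclass
class DisplacementHistory:
    """Rigid-motion time series: translations ``u0`` [m], rotations ``theta`` [rad]."""

    t_grid: np.ndarray
    u0: np.ndarray
    theta: np.ndarray

    def __post_init__(self) -> None:
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        self.u0 = np.asarray(self.u0, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        n = self.t_grid.size
        if self.t_grid[0] < 0 or np.any(np.diff(self.t_grid) <= 0):
            raise ValueError("t_grid must be nonnegative and strictly increasing")
        if self.u0.shape != (n, 3) or self.theta.shape != (n, 3):
            raise ValueError("u0 and theta must have shape (n_t, 3)")
        if not (np.all(np.isfinite(self.u0)) and np.all(np.isfinite(self.theta))):
            raise ValueError("history values must be finite")

    @property
    def q(self) -> np.ndarray:
        """Stacked (n_t, 6) generalized coordinates."""
        return np.hstack([self.u0, self.theta])


def default_time_grid(t_min: float = 1e-6, t_max: float = 300.0, n: int = 600) -> np.ndarray:
    """Geometric time grid resolving the weakly singular early response.

    The creep solution rises like ``t^gamma`` out of ``t = 0``; starting the
    grid well below the observation window keeps the interpolation error of
    that initial burst out of the late-time solution.
    """
    return np.geomspace(t_min, t_max, n)


# ---------------------------------------------------------------------------
# Closed-form constant-load solutions
# ---------------------------------------------------------------------------


def _history_single(t_grid, values, index: int) -> DisplacementHistory:
    t_grid = np.asarray(t_grid, dtype=float)
    u0 = np.zeros((t_grid.size, 3))
    u0[:, index] = values
    return DisplacementHistory(t_grid=t_grid, u0=u0, theta=np.zeros_like(u0))


def vertical_creep(
    f_y: float,
    a22: float,
    kernel: FractionalKernel,
    t_grid=None,
    form: str = "rabotnov",
) -> DisplacementHistory:
    """Vertical (intrusion/extrusion) translation under constant ``f_y``.

    ``u0y(t) = (f_y / a22) c(t)`` with ``u0y(0) = f_y / a22``.
    """
    if not a22 > 0:
        raise ValueError("a22 must be positive")
    t_grid = default_time_grid() if t_grid is None else np.asarray(t_grid, dtype=float)
    c = creep_factor(t_grid, kernel, form=form)
    return _history_single(t_grid, f_y / a22 * c, index=1)


def horizontal_creep(
    f_x: float,
    S: StiffnessMatrix,
    kernel: FractionalKernel,
    t_grid=None,
    y_f: float | None = None,
    form: str = "rabotnov",
) -> tuple[DisplacementHistory, dict]:
    """Pure horizontal translation along ``x`` under a force through the
    centre of resistance.

    Returns the history and a consistency report: the rotational equation
    ``a61 L[u0x] = -y_f f_x`` is satisfied identically iff the load line
    passes through ``y1 = -a61/a11``.  If ``y_f`` deviates from ``y1`` the
    pure-translation assumption is broken and the report carries the
    relative moment imbalance.
    """
    t_grid = default_time_grid() if t_grid is None else np.asarray(t_grid, dtype=float)
    y1, _ = center_of_resistance(S)
    if y_f is None:
        y_f = y1
    c = creep_factor(t_grid, kernel, form=form)
    hist = _history_single(t_grid, f_x / S.a11 * c, index=0)
    # L[u0x] = f_x/a11 exactly, so the moment equation reads a61 f_x / a11 = -y_f f_x
    moment_residual = abs(-S.a61 / S.a11 - y_f) * abs(f_x)
    report = {
        "y1": y1,
        "y_f": y_f,
        "moment_residual": moment_residual,
        "consistent": bool(abs(y_f - y1) <= 1e-9 * max(abs(y1), 1e-300)),
    }
    return hist, report


def max_normal_cosine(geom: RootGeometry, direction: str, n_search: int = 512) -> float:
    """Surface maximum of the normal's direction cosine along an axis.

    For vertical translation the maximum is 1 at the apex; for horizontal
    translation it is located on a dense ``(r, phi)`` grid including the
    crest ring, where it peaks (at the crest meridian point for ``x``).
    """
    if direction == "y":
        return 1.0
    idx = {"x": 0, "z": 2}[direction]
    r = np.linspace(0.0, 1.0, n_search)
    phi = np.linspace(0.0, 2 * np.pi, 2 * n_search, endpoint=False)
    R, PHI = np.meshgrid(r, phi, indexing="ij")
    x = geom.a * R * np.cos(PHI)
    z = geom.b * R * np.sin(PHI)
    D = geom.Delta(x, z)
    comp = 2 * (1 - geom.e**2) * geom.h * x if idx == 0 else 2 * geom.h * z
    return float(np.max(np.abs(comp) / (geom.b**2 * D)))


def required_force(
    target_un: float,
    direction: str,
    t_eval: float,
    S: StiffnessMatrix,
    kernel: FractionalKernel,
    geom: RootGeometry,
    form: str = "rabotnov",
) -> float:
    """Force magnitude driving the peak normal compression ``|u . n|`` of the
    ligament to ``target_un`` at time ``t_eval``.

    For a pure translation along ``direction`` the normal penetration per
    unit force is ``c(t) max|n_dir| / a_dir``, so the force is linear in the
    target.
    """
    if target_un <= 0:
        raise ValueError("target penetration must be positive")
    diag = {"x": S.a11, "y": S.a22, "z": S.a33}[direction]
    n_max = max_normal_cosine(geom, direction)
    c = float(creep_factor(t_eval, kernel, form=form))
    return target_un * diag / (c * n_max)


# ---------------------------------------------------------------------------
# Product-integration Volterra solver
# ---------------------------------------------------------------------------


class _ProductIntegrator:
    """Exact product-integration weights for the Rabotnov convolution.

    For piecewise-linear data ``q`` on the grid the convolution
    ``int_0^{t_i} kernel(t_i - theta) q(theta) dtheta`` needs, per cell, the
    kernel mass ``I0`` and first moment.  Both follow from the kernel
    primitive ``E(s) = E_ml(-(s/tau_eps)^gamma)`` (``int kernel = -dE``) and
    its integral ``P(s) = int_0^s E``:

        I0 = E(s_a) - E(s_b),
        int_{s_a}^{s_b} s kernel(s) ds = s_a E(s_a) - s_b E(s_b) + P(s_b) - P(s_a),

    with ``s = t_i - theta``.  ``E`` and ``P`` are tabulated on a log grid
    spanning from far below the relaxation time (where ``E ~ 1``,
    ``P ~ s``) up to the horizon, and splined; the boundary layer of width
    ``tau_eps`` is fully resolved no matter how coarse the time grid is.
    """

    def __init__(self, kernel: FractionalKernel, s_max: float, n_table: int = 3000):
        kernel = convert_creep_relax(kernel)
        self.kernel = kernel
        s_lo = min(1e-6 * kernel.tau_eps, 1e-6 * s_max)
        s = np.geomspace(s_lo, s_max * (1 + 1e-9), n_table)
        E = mittag_leffler_neg((s / kernel.tau_eps) ** kernel.gamma, kernel.gamma)
        P = np.empty_like(s)
        P[0] = s[0]  # E ~ 1 below the table
        P[1:] = s[0] + np.cumsum(0.5 * (E[1:] + E[:-1]) * np.diff(s))
        self._logs = np.log(s)
        self._E = CubicSpline(self._logs, E)
        self._P = CubicSpline(self._logs, P)
        self._s_lo = s[0]

    def E(self, s):
        s = np.asarray(s, dtype=float)
        out = np.ones_like(s)
        m = s > self._s_lo
        out[m] = self._E(np.log(s[m]))
        return out

    def P(self, s):
        s = np.asarray(s, dtype=float)
        out = s.copy()
        m = s > self._s_lo
        out[m] = self._P(np.log(s[m]))
        return out

    def node_weights(self, t_nodes: np.ndarray, i: int) -> np.ndarray:
        """Coefficients ``w_j`` with ``conv(t_i) = sum_{j<=i} w_j q_j`` for
        piecewise-linear ``q`` on ``t_nodes[: i + 1]``."""
        t = t_nodes[: i + 1]
        ti = t[-1]
        s = ti - t  # descending, s[-1] = 0
        Ev = self.E(s)
        Pv = self.P(s)
        s_b, s_a = s[:-1], s[1:]  # per cell: b = older node, a = newer
        I0 = Ev[1:] - Ev[:-1]  # E(s_a) - E(s_b) > 0
        # int_{s_a}^{s_b} s kernel(s) ds, by parts against -E:
        J1 = s_a * Ev[1:] - s_b * Ev[:-1] + Pv[:-1] - Pv[1:]
        dt = np.diff(t)
        beta = ((ti - t[:-1]) * I0 - J1) / dt  # weight on the newer node
        w = np.zeros(i + 1)
        w[:-1] += I0 - beta
        w[1:] += beta
        return w


def volterra_solve(
    S: StiffnessMatrix,
    load,
    kernel: FractionalKernel,
    t_grid=None,
) -> DisplacementHistory:
    """Solve the coupled quasi-static system ``A L[q](t) = g(t)`` numerically.

    ``load`` is a :class:`LoadCase` (held constant) or a callable
    ``t -> 6-vector``.  The convolution is discretized by product
    integration: the solution is piecewise linear on the grid and the
    kernel is integrated exactly over each cell through its Mittag-Leffler
    primitive, so the scheme keeps first-order-plus accuracy despite the
    weak singularity and the short relaxation time.  The grid is prepended
    with ``t = 0``, where the response is the elastic one ``A q = g(0)``.
    """
    kernel = convert_creep_relax(kernel)
    t_grid = default_time_grid() if t_grid is None else np.asarray(t_grid, dtype=float)
    if t_grid[0] <= 0:
        raise ValueError("first grid node must be positive (t = 0 is added internally)")
    if callable(load):
        g_of_t = load
    else:
        g_const = load.generalized()
        g_of_t = lambda t: g_const  # noqa: E731

    t = np.concatenate([[0.0], t_grid])
    n = t.size
    A = S.system_matrix()
    nu_e = kernel.nu_eps
    integ = _ProductIntegrator(kernel, s_max=t[-1])

    from scipy.linalg import lu_factor, lu_solve

    lu_piv = lu_factor(A)

    q = np.zeros((n, 6))
    q[0] = lu_solve(lu_piv, g_of_t(0.0))
    for i in range(1, n):
        w = integ.node_weights(t, i)
        hist = (w[:-1, None] * q[:i]).sum(axis=0)
        rhs = lu_solve(lu_piv, g_of_t(t[i])) + nu_e * hist
        q[i] = rhs / (1.0 - nu_e * w[-1])

    return DisplacementHistory(t_grid=t, u0=q[:, :3], theta=q[:, 3:])


def volterra_residual(
    history: DisplacementHistory,
    S: StiffnessMatrix,
    load,
    kernel: FractionalKernel,
) -> np.ndarray:
    """Residual ``A L[q] - g`` [N or N m] of each equation at each grid node,
    evaluated with the same product-integration discretization as the solver."""
    kernel = convert_creep_relax(kernel)
    t = history.t_grid
    q = history.q
    if callable(load):
        g_of_t = load
    else:
        g_const = load.generalized()
        g_of_t = lambda tt: g_const  # noqa: E731
    A = S.system_matrix()
    integ = _ProductIntegrator(kernel, s_max=t[-1])
    res = np.zeros((t.size, 6))
    for i in range(t.size):
        if t[i] == 0:
            conv = np.zeros(6)
        else:
            w = integ.node_weights(t, i)
            conv = (w[:, None] * q[: i + 1]).sum(axis=0)
        res[i] = A @ (q[i] - kernel.nu_eps * conv) - g_of_t(t[i])
    return res


# ---------------------------------------------------------------------------
# Inertia assessment
# ---------------------------------------------------------------------------


def inertia_estimate(
    t,
    f: float,
    a_diag: float,
    kernel: FractionalKernel,
    M: float = ROOT_MASS,
) -> dict:
    """Acceleration of the constant-load creep solution and the inertial term.

    The second time derivative of ``u(t) = (f/a) c(t)`` is evaluated
    analytically term-by-term from the creep series,

        c''(t) = nu_sigma * sum_m (-1)^(m-1) gm (gm - 1) t^(gm-2)
                 / (tau_sigma^gm Gamma(gm)),   gm = gamma m,

    which is singular at ``t = 0`` (the solution rises like ``t^gamma``);
    evaluation therefore requires ``t > 0``.  Returns the acceleration
    profile [m/s^2], the inertial force ``M u''`` [N] and the elastic force
    scale ``a |u|`` [N] for the quasi-static comparison.
    """
    kernel = convert_creep_relax(kernel)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise ValueError("acceleration of the creep solution is singular at t = 0")
    g, tau, nus = kernel.gamma, kernel.tau_sigma, kernel.nu_sigma
    cpp = np.zeros_like(t_arr)
    for m in range(1, kernel.n_max + 1):
        gm = g * m
        term = (-1.0) ** (m - 1) * gm * (gm - 1.0) * t_arr ** (gm - 2.0) / (tau**gm * _gamma(gm))
        cpp += term
        if np.max(np.abs(term)) < kernel.tol * max(np.max(np.abs(cpp)), 1e-300) and m > 2:
            break
    accel = f / a_diag * nus * cpp
    u = f / a_diag * creep_factor(t_arr, kernel)
    return {
        "t": t_arr,
        "acceleration": accel,
        "inertial_force": M * accel,
        "elastic_force": a_diag * np.abs(u),
    }
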