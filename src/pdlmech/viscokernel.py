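"""Rabotnov fractional-exponential kernel and its creep/relaxation algebra.

The stress-relaxation kernel of the constitutive law is the Rabotnov
fractional-exponential function

    E_gamma(-t/tau) = t^(gamma-1)/tau^gamma
                      * sum_{n>=0} (-1)^n (t/tau)^(gamma n) / Gamma(gamma (n+1)),

a weakly singular, completely monotone kernel that reduces to the plain
exponential ``exp(-t/tau)/tau`` at ``gamma = 1``.  It is related to the
Mittag-Leffler function through
``E_gamma(-t/tau) = -d/dt E_ML_gamma(-(t/tau)^gamma)``.

Two parameter pairs describe the same material: the relaxation pair
``(nu_eps, tau_eps)`` entering the constitutive convolution, and the creep
(retardation) pair ``(nu_sigma, tau_sigma)`` entering the displacement
solution under constant load.  They are linked by the operator-inversion
algebra

    nu_eps  = nu_sigma / (1 + nu_sigma),
    tau_eps = tau_sigma * (1 - nu_eps)^(1/gamma),

with ``nu_eps = (E_inf - E_0)/E_inf`` and ``nu_sigma = (E_inf - E_0)/E_0``
in terms of the instantaneous (E_0) and relaxed (E_inf) moduli.  (E_0 is
the larger modulus here; with the moduli-difference convention used
throughout the model both nu values come out positive.)

Creep factor
------------
:func:`creep_factor` returns the dimensionless multiplier ``c(t)`` of the
constant-load displacement solution ``u(t) = (f/a) c(t)``.  Two analytic
forms are provided:

``form="rabotnov"`` (default)
    ``c(t) = 1 + nu_sigma * sum_{m>=1} (-1)^(m-1) (t/tau_sigma)^(gamma m)
    / Gamma(gamma m)``, i.e. ``1 + nu_sigma * t * E_gamma(-t/tau_sigma)``.
    This is the closed form the model's headline time-evolution factors
    (1.75 at 10 s, 2.55 at 300 s relative to 1 s) follow from.

``form="mittag-leffler"``
    ``c(t) = 1 + nu_sigma * (1 - E_ML_gamma(-(t/tau_sigma)^gamma))``, the
    exact resolvent of the relaxation-form Volterra operator: substituted
    back into the constitutive equation it leaves zero residual (see
    :func:`relaxation_residual`).  The two forms differ by a unit shift in
    the Gamma arguments and are *not* equal for gamma < 1; the discrepancy
    is documented in the methods note.

The creep series prefactor defaults to the dimensionless ``(t/tau)^gamma``;
``prefactor="dimensional"`` reproduces the dimensionally inhomogeneous
variant ``t^gamma / tau`` for comparison purposes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import quad
from scipy.special import gamma as _gamma

__all__ = [
    "FractionalKernel",
    "rabotnov",
    "mittag_leffler_neg",
    "creep_factor",
    "convert_creep_relax",
    "truncation_order",
    "relaxation_residual",
]


@dataclass(frozen=True)
class FractionalKernel:
    """Rabotnov kernel parameters in creep (sigma) and/or relaxation (eps) form.

    At least one of the pairs ``(nu_sigma, tau_sigma)`` / ``(nu_eps,
    tau_eps)`` must be given; :func:`convert_creep_relax` fills in the other.
    ``tol`` and ``n_max`` control series truncation.
    """

    gamma: float
    tau_sigma: float | None = None
    nu_sigma: float | None = None
    tau_eps: float | None = None
    nu_eps: float | None = None
    n_max: int = 200
    tol: float = 1e-10

    def __post_init__(self) -> None:
        if not 0 < self.gamma <= 1:
            raise ValueError(f"fractional parameter gamma must be in (0, 1], got {self.gamma}")
        has_sigma = self.tau_sigma is not None and self.nu_sigma is not None
        has_eps = self.tau_eps is not None and self.nu_eps is not None
        if not (has_sigma or has_eps):
            raise ValueError("provide a complete (nu_sigma, tau_sigma) or (nu_eps, tau_eps) pair")
        if self.tau_sigma is not None and self.tau_sigma <= 0:
            raise ValueError("tau_sigma must be positive")
        if self.tau_eps is not None and self.tau_eps <= 0:
            raise ValueError("tau_eps must be positive")
        if self.nu_sigma is not None and self.nu_sigma <= 0:
            raise ValueError("nu_sigma must be positive")
        if self.nu_eps is not None and not 0 < self.nu_eps < 1:
            raise ValueError("nu_eps must be in (0, 1)")

    @classmethod
    def from_moduli(
        cls, gamma: float, e_0: float, e_inf: float, tau_sigma: float, **kw
    ) -> "FractionalKernel":
        """Build from instantaneous/relaxed moduli (``e_0 > e_inf > 0``)."""
        if not e_0 > e_inf > 0:
            raise ValueError("moduli must satisfy E_0 > E_inf > 0")
        nu_sigma = (e_0 - e_inf) / e_inf
        return convert_creep_relax(cls(gamma=gamma, tau_sigma=tau_sigma, nu_sigma=nu_sigma, **kw))


def convert_creep_relax(kernel: FractionalKernel) -> FractionalKernel:
    """Fill in the missing parameter pair from the operator-inversion algebra.

    The relaxation-form Volterra operator ``L[u] = u - nu_eps * conv(E_eps, u)``
    has resolvent ``L^-1[g] = g + nu_sigma * conv(E_sigma, g)`` (with the
    integrated creep kernel in Mittag-Leffler form) exactly when

        nu_sigma = nu_eps / (1 - nu_eps),
        tau_sigma^(-gamma) = (1 - nu_eps) * tau_eps^(-gamma).

    The round trip sigma -> eps -> sigma is the identity.
    """
    g = kernel.gamma
    if kernel.nu_sigma is not None and kernel.tau_sigma is not None:
        nu_eps = kernel.nu_sigma / (1.0 + kernel.nu_sigma)
        tau_eps = kernel.tau_sigma * (1.0 - nu_eps) ** (1.0 / g)
        if kernel.nu_eps is not None and not np.isclose(kernel.nu_eps, nu_eps, rtol=1e-9):
            raise ValueError("inconsistent nu_sigma / nu_eps pair")
        return replace(kernel, nu_eps=nu_eps, tau_eps=tau_eps)
    nu_sigma = kernel.nu_eps / (1.0 - kernel.nu_eps)
    tau_sigma = kernel.tau_eps * (1.0 - kernel.nu_eps) ** (-1.0 / g)
    return replace(kernel, nu_sigma=nu_sigma, tau_sigma=tau_sigma)


# ---------------------------------------------------------------------------
# Mittag-Leffler machinery (negative real axis only)
# ---------------------------------------------------------------------------

_SERIES_CUTOFF = 1.0  # |arg| below which the Taylor series is used


def _ml_neg_series(y: float, g: float, tol: float = 1e-16, n_max: int = 300) -> float:
    total = 0.0
    for k in range(n_max):
        term = (-1.0) ** k * y**k / _gamma(g * k + 1.0)
        total += term
        if abs(term) < tol * max(abs(total), 1e-300) and k > 0:
            break
    return total


def _ml_neg_integral(y: float, g: float) -> float:
    """Spectral representation, valid for all y > 0, 0 < gamma < 1.

    ``E_gamma(-t^gamma) = sin(gamma pi)/(gamma pi) *
    int_0^inf exp(-t v^(1/gamma)) / (v^2 + 2 v cos(gamma pi) + 1) dv``
    with ``t = y^(1/gamma)``.
    """
    t = y ** (1.0 / g)
    cg = np.cos(g * np.pi)
    sg = np.sin(g * np.pi)

    def f(v):
        return np.exp(-t * v ** (1.0 / g)) / (v * v + 2 * v * cg + 1.0)

    # exp factor is ~1e-20 beyond v = (46/t)^gamma; integrating further only
    # dilutes the quadrature (for large t the whole mass sits in a narrow
    # layer near v = 0 that a wide interval would miss).
    upper = (46.0 / t) ** g
    val, _ = quad(f, 0.0, upper, limit=200, epsabs=1e-14, epsrel=1e-12)
    return sg / (g * np.pi) * val


def mittag_leffler_neg(y, gamma: float):
    """One-parameter Mittag-Leffler function ``E_gamma(-y)`` for ``y >= 0``.

    Uses the Taylor series for small arguments and the completely monotone
    spectral (integral) representation otherwise; at ``gamma = 1`` it is
    ``exp(-y)``.  Vectorized in ``y``.
    """
    y_arr = np.asarray(y, dtype=float)
    if np.any(y_arr < 0):
        raise ValueError("argument must be nonnegative")
    if gamma == 1.0:
        out = np.exp(-y_arr)
        return out if y_arr.shape else float(out)
    out = np.empty_like(y_arr)
    flat = y_arr.ravel()
    res = out.ravel()
    for i, yi in enumerate(flat):
        if yi <= _SERIES_CUTOFF:
            res[i] = _ml_neg_series(yi, gamma)
        else:
            res[i] = _ml_neg_integral(yi, gamma)
    return out if y_arr.shape else float(out)


def rabotnov(t, gamma: float, tau: float, tol: float = 1e-12, n_max: int = 300):
    """Rabotnov kernel ``E_gamma(-t/tau)`` [1/s]; requires ``t > 0``.

    The defining alternating series is summed for moderate arguments
    (``t/tau <= 2``); for larger arguments the spectral representation of
    the equivalent Mittag-Leffler form is integrated instead (the series
    suffers catastrophic cancellation there).
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise ValueError("the kernel is singular/undefined for t <= 0 (gamma < 1)")
    g = gamma
    x = t_arr / tau
    out = np.empty_like(x)
    flat_x, flat_t, res = x.ravel(), t_arr.ravel(), out.ravel()
    for i, (xi, ti) in enumerate(zip(flat_x, flat_t)):
        if xi <= 2.0:
            total = 0.0
            for n in range(n_max):
                term = (-1.0) ** n * xi ** (g * n) / _gamma(g * (n + 1))
                total += term
                if abs(term) < tol * max(abs(total), 1e-300) and n > 0:
                    break
            res[i] = ti ** (g - 1.0) / tau**g * total
        else:
            # E(t) = -d/dt ML(-(t/tau)^gamma), via the spectral density
            cg, sg = np.cos(g * np.pi), np.sin(g * np.pi)

            def f(v, u=xi):
                return v ** (1.0 / g) * np.exp(-u * v ** (1.0 / g)) / (v * v + 2 * v * cg + 1.0)

            upper = (46.0 / xi) ** g
            val, _ = quad(f, 0.0, upper, limit=200, epsabs=1e-16, epsrel=1e-12)
            res[i] = sg / (g * np.pi * tau) * val
    return out if x.shape else float(out)


# ---------------------------------------------------------------------------
# Creep factor
# ---------------------------------------------------------------------------


def _creep_series_sum(x, gamma: float, tol: float, n_max: int, n_terms: int | None = None):
    """``S(x) = sum_{m>=1} (-1)^(m-1) x^(gamma m) / Gamma(gamma m)`` (vectorized)."""
    x = np.asarray(x, dtype=float)
    total = np.zeros_like(x)
    mask = x > 0
    last = n_terms if n_terms is not None else n_max
    for m in range(1, last + 1):
        term = np.zeros_like(x)
        term[mask] = (-1.0) ** (m - 1) * x[mask] ** (gamma * m) / _gamma(gamma * m)
        total += term
        if n_terms is None and m > 1:
            scale = np.max(np.abs(total)) or 1e-300
            if np.max(np.abs(term)) < tol * scale:
                break
    return total


def creep_factor(
    t,
    kernel: FractionalKernel,
    form: str = "rabotnov",
    prefactor: str = "dimensionless",
    n_terms: int | None = None,
):
    """Dimensionless creep multiplier ``c(t)`` with ``c(0) = 1``.

    See the module docstring for the two analytic forms.  ``n_terms`` forces
    a fixed truncation of the ``"rabotnov"`` series (for truncation
    studies); by default the series is summed to the kernel's ``tol``.
    """
    kernel = convert_creep_relax(kernel)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be nonnegative")
    g, tau, nus = kernel.gamma, kernel.tau_sigma, kernel.nu_sigma
    if form == "rabotnov":
        s = _creep_series_sum(t_arr / tau, g, kernel.tol, kernel.n_max, n_terms)
        if prefactor == "dimensional":
            # literal reading t^gamma / tau: rescales every term by tau^(gamma-1)
            s = s * tau ** (g - 1.0)
        elif prefactor != "dimensionless":
            raise ValueError(f"unknown prefactor reading: {prefactor!r}")
        c = 1.0 + nus * s
    elif form == "mittag-leffler":
        c = 1.0 + nus * (1.0 - mittag_leffler_neg((t_arr / tau) ** g, g))
    else:
        raise ValueError(f"unknown creep form: {form!r}")
    return c if t_arr.shape else float(c)


def truncation_order(
    gamma: float,
    t_max: float,
    tau: float,
    tol: float,
    nu_sigma: float | None = None,
    n_cap: int = 400,
) -> int:
    """Smallest series order ``n`` beyond which ``c(t_max)`` changes by < ``tol``.

    The change is measured relative to the converged creep factor; if
    ``nu_sigma`` is omitted the relative change of the bare series sum is
    used (the two agree whenever ``nu_sigma * S >> 1``, as in all scenarios
    of interest here).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    x = np.asarray([t_max / tau])
    ref = _creep_series_sum(x, gamma, 1e-16, n_cap, n_terms=n_cap)[0]
    denom = abs(1.0 + nu_sigma * ref) / nu_sigma if nu_sigma else abs(ref)
    for n in range(1, n_cap):
        part = _creep_series_sum(x, gamma, 1e-16, n_cap, n_terms=n)[0]
        if abs(part - ref) < tol * denom:
            return n
    return n_cap


# ---------------------------------------------------------------------------
# Residual of the relaxation-form Volterra equation
# ---------------------------------------------------------------------------


def relaxation_residual(t: float, kernel: FractionalKernel, form: str = "mittag-leffler") -> float:
    """Residual ``|c(t) - nu_eps * conv(E_eps, c)(t) - 1|`` of the constitutive
    Volterra equation under constant unit load.

    The convolution is evaluated semi-analytically: integrating by parts
    against the Mittag-Leffler primitive of the kernel removes the weak
    singularity, and the remaining integral is regularized with the
    substitution ``v = theta^gamma`` so that the integrand is smooth.  For
    the exact resolvent form the residual is at numerical round-off; for the
    ``"rabotnov"`` closed form it quantifies that form's departure from the
    constitutive equation.
    """
    kernel = convert_creep_relax(kernel)
    g, tau_e, nu_e = kernel.gamma, kernel.tau_eps, kernel.nu_eps
    tau_s, nu_s = kernel.tau_sigma, kernel.nu_sigma
    if t <= 0:
        raise ValueError("t must be positive")

    def E_eps(s):
        return mittag_leffler_neg((s / tau_e) ** g, g)

    # conv(E_eps, c)(t) = c(t) - E_eps(t) - int_0^t E_eps(s) c'(t - s) ds,
    # using c(0) = 1 and E_eps(0) = 1.  The remaining integral has two
    # delicate regions: s ~ tau_eps (the kernel primitive E_eps falls from 1
    # within the very short relaxation time) and s ~ t (where c'(t-s) is
    # weakly singular).  Split at t/2 and regularize each part separately.
    if form == "rabotnov":
        weight = lambda m: g * m  # noqa: E731  (series derivative weight)
    elif form == "mittag-leffler":
        weight = lambda m: 1.0  # noqa: E731  (c' is the Rabotnov kernel)
    else:
        raise ValueError(f"unknown creep form: {form!r}")

    def dc_series(v):
        # c'(theta) dtheta in the variable v = theta^gamma (smooth in v)
        total = 0.0
        for m in range(1, kernel.n_max + 1):
            term = (-1.0) ** (m - 1) * weight(m) * v ** (m - 1) / (tau_s ** (g * m) * _gamma(g * m))
            total += term
            if abs(term) < 1e-18 * max(abs(total), 1e-300) and m > 2:
                break
        return nu_s * total / g

    def dc(theta):
        return dc_series(theta**g) * g * theta ** (g - 1.0)

    # s in (0, t/2]: log substitution s = exp(xi) resolves the kernel layer;
    # the truncated tail below s_lo contributes < s_lo * max|c'| ~ 1e-12.
    s_lo = 1e-14 * t

    def f_low(xi):
        s = np.exp(xi)
        return E_eps(s) * dc(t - s) * s

    low, _ = quad(f_low, np.log(s_lo), np.log(t / 2.0), limit=400, epsabs=1e-10, epsrel=1e-10)

    # s in [t/2, t): v = (t-s)^gamma removes the c' singularity; E_eps is
    # smooth (power-law) on this range.
    def f_high(v):
        return E_eps(t - v ** (1.0 / g)) * dc_series(v)

    high, _ = quad(f_high, 0.0, (t / 2.0) ** g, limit=400, epsabs=1e-10, epsrel=1e-10)

    c_t = float(creep_factor(t, kernel, form=form))
    conv = c_t - E_eps(t) - (low + high)
    return abs(c_t - nu_e * conv - 1.0)
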