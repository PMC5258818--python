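"""Dispersal kernels, dispersal-success approximations, and critical lengths.

A population on a bounded one-dimensional habitat ``[-L/2, L/2]`` loses the
offspring that settle outside it.  For a symmetric dispersal kernel
``k(x, y)`` the probability that an individual dispersing from ``y`` lands
inside the habitat is the settlement probability

    s(y) = int_{-L/2}^{L/2} k(x, y) dx.

Averaging s over the habitat gives the average dispersal success ``S``;
re-weighting by the (approximate) population distribution ``s(y)/S`` gives
the modified dispersal success ``S_hat >= S``, which is the retention
proportion used by the spatially implicit approximations in the rest of
the package.  This module also solves two critical-length problems: the
deterministic one (dominant eigenvalue of the linear growth-dispersal
operator equal to 1, by a Nystrom discretization) and the inversion of
``S_hat(L)`` at a target retention.

All lengths are expressed in multiples of the mean dispersal distance
``b``; the Laplace kernel with scale ``b`` has mean absolute displacement
``b`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.integrate import quad
from scipy.sparse.linalg import eigsh
from scipy.optimize import brentq

__all__ = [
    "DispersalKernel",
    "Domain",
    "DispersalSuccess",
    "laplace_kernel",
    "kernel_density",
    "settlement_probability",
    "average_success",
    "modified_success",
    "success_variances",
    "dispersal_success_summary",
    "invert_modified_success",
    "dominant_eigenvalue",
    "ide_critical_length",
    "laplace_critical_length_analytic",
]

_QUAD_TOL = 1e-10


@dataclass(frozen=True)
class DispersalKernel:
    """Symmetric displacement kernel with mean dispersal distance ``b``.

    ``family`` is ``"laplace"`` (closed forms available) or ``"custom"``,
    in which case ``density_fn`` (an even probability density of the signed
    displacement) and optionally ``sampler_fn`` must be supplied.
    """

    family: str
    b: float
    density_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None
    sampler_fn: Optional[Callable[[np.random.Generator, int], np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("mean dispersal distance b must be positive")
        if self.family not in ("laplace", "custom"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family == "custom" and self.density_fn is None:
            raise ValueError("custom kernels require a density function")

    def density(self, u):
        """Density of the signed displacement ``u = x - y``."""
        u = np.asarray(u, dtype=float)
        if self.family == "laplace":
            return np.exp(-np.abs(u) / self.b) / (2.0 * self.b)
        return self.density_fn(u)

    def sample(self, rng: np.random.Generator, size=None):
        """Draw iid displacements."""
        if self.family == "laplace":
            return rng.laplace(loc=0.0, scale=self.b, size=size)
        if self.sampler_fn is None:
            raise NotImplementedError("custom kernel has no sampler")
        return self.sampler_fn(rng, size)

    def mean_abs_displacement(self) -> float:
        if self.family == "laplace":
            return self.b
        val, _ = quad(lambda u: u * self.density(u), 0, np.inf)
        return 2.0 * val


def laplace_kernel(b: float = 1.0) -> DispersalKernel:
    """Laplace kernel (1/(2b)) exp(-|x-y|/b), scale b = sqrt(D/alpha)."""
    return DispersalKernel(family="laplace", b=b)


@dataclass(frozen=True)
class Domain:
    """Habitat interval [-L/2, L/2] of length L > 0."""

    L: float

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("domain length L must be positive")

    @property
    def half(self) -> float:
        return self.L / 2.0


@dataclass(frozen=True)
class DispersalSuccess:
    """Retention summary for a kernel on a domain.

    ``var_S`` and ``var_S_hat`` are the un-normalized integrals
    int (s - S)^2 dy and int (s^2/S - S_hat)^2 dy over the domain (see
    :func:`success_variances`).
    """

    L: float
    S: float
    S_hat: float
    var_S: float
    var_S_hat: float


def kernel_density(kernel: DispersalKernel, x, y):
    """Kernel density k(x, y) as a function of two locations."""
    return kernel.density(np.asarray(x, dtype=float) - np.asarray(y, dtype=float))


def settlement_probability(kernel: DispersalKernel, domain: Domain, y):
    """Probability s(y) that a disperser from ``y`` settles in the domain."""
    y = np.asarray(y, dtype=float)
    a = domain.half
    if kernel.family == "laplace":
        b = kernel.b
        out = 1.0 - 0.5 * np.exp(-(a - y) / b) - 0.5 * np.exp(-(a + y) / b)
        # closed form is the integral, valid for |y| <= a; outside the
        # domain the two exponentials must be re-derived, so fall back.
        if np.any(np.abs(y) > a):
            return _settlement_quadrature(kernel, domain, y)
        return out if out.ndim else float(out)
    return _settlement_quadrature(kernel, domain, y)


def _settlement_quadrature(kernel, domain, y):
    a = domain.half

    def one(yy):
        val, _ = quad(
            lambda x: kernel.density(x - yy), -a, a, epsabs=_QUAD_TOL, epsrel=_QUAD_TOL
        )
        return val

    y = np.atleast_1d(y)
    out = np.array([one(yy) for yy in y])
    return out if out.size > 1 else float(out[0])


def average_success(kernel: DispersalKernel, domain: Domain) -> float:
    """Average dispersal success S = (1/L) int s(y) dy over the domain."""
    L, a = domain.L, domain.half
    if kernel.family == "laplace":
        b = kernel.b
        return float(1.0 - (b / L) * (1.0 - np.exp(-L / b)))
    val, _ = quad(
        lambda y: settlement_probability(kernel, domain, y),
        -a,
        a,
        epsabs=_QUAD_TOL,
        epsrel=_QUAD_TOL,
    )
    return val / L


def _integral_s_squared(kernel: DispersalKernel, domain: Domain) -> float:
    """int_{-L/2}^{L/2} s(y)^2 dy, closed form for Laplace."""
    L, a = domain.L, domain.half
    if kernel.family == "laplace":
        b = kernel.b
        e1 = np.exp(-L / b)
        e2 = np.exp(-2.0 * L / b)
        return float(L - 2.0 * b * (1.0 - e1) + 0.25 * b * (1.0 - e2) + 0.5 * L * e1)
    val, _ = quad(
        lambda y: settlement_probability(kernel, domain, y) ** 2,
        -a,
        a,
        epsabs=_QUAD_TOL,
        epsrel=_QUAD_TOL,
    )
    return val


def modified_success(kernel: DispersalKernel, domain: Domain) -> float:
    """Modified dispersal success S_hat = (1/(L S)) int s(y)^2 dy.

    Weights each location's success by the relative density s(y)/S of
    settlers expected there, so S_hat >= S for symmetric kernels.
    """
    S = average_success(kernel, domain)
    if S <= 0.0:
        raise ValueError("domain too small: average success is zero")
    return _integral_s_squared(kernel, domain) / (domain.L * S)


def success_variances(
    kernel: DispersalKernel, domain: Domain, normalized: bool = False
) -> tuple[float, float]:
    """Variance integrals of the dispersal-success approximations.

    Returns ``(var_S, var_S_hat)`` with

        var_S     = int (s(y) - S)^2 dy,
        var_S_hat = int (s(y)^2/S - S_hat)^2 dy,

    taken over the domain.  With ``normalized=True`` both integrals are
    divided by L, the variance of s (resp. s^2/S) under a uniform location.
    """
    a = domain.half
    S = average_success(kernel, domain)
    if S <= 0.0:
        raise ValueError("domain too small: average success is zero")
    S_hat = modified_success(kernel, domain)

    def s(y):
        return settlement_probability(kernel, domain, y)

    var_S, _ = quad(lambda y: (s(y) - S) ** 2, -a, a, epsabs=_QUAD_TOL, epsrel=_QUAD_TOL)
    var_S_hat, _ = quad(
        lambda y: (s(y) ** 2 / S - S_hat) ** 2, -a, a, epsabs=_QUAD_TOL, epsrel=_QUAD_TOL
    )
    if normalized:
        return var_S / domain.L, var_S_hat / domain.L
    return var_S, var_S_hat


def dispersal_success_summary(kernel: DispersalKernel, domain: Domain) -> DispersalSuccess:
    """Full retention summary (S, S_hat and their variance integrals)."""
    var_S, var_S_hat = success_variances(kernel, domain)
    return DispersalSuccess(
        L=domain.L,
        S=average_success(kernel, domain),
        S_hat=modified_success(kernel, domain),
        var_S=var_S,
        var_S_hat=var_S_hat,
    )


def invert_modified_success(
    kernel: DispersalKernel, target: float, bracket: tuple[float, float] | None = None
) -> float:
    """Domain length L at which S_hat(L) equals ``target``.

    S_hat is strictly increasing in L with range (0, 1), so the root is
    unique; it is found by bracketed root finding to |S_hat - target| below
    1e-10.
    """
    if not 0.0 < target < 1.0:
        raise ValueError("target retention must lie strictly between 0 and 1")
    lo, hi = bracket if bracket is not None else (1e-6 * kernel.b, 100.0 * kernel.b)

    def g(L):
        return modified_success(kernel, Domain(L)) - target

    while g(hi) < 0.0:  # pragma: no cover - generous default bracket
        hi *= 2.0
    return float(brentq(g, lo, hi, xtol=1e-12, rtol=8.9e-16))


def _default_nodes(L: float, b: float) -> int:
    # the kernel kink along x = y slows Gauss-Legendre convergence, so the
    # node density is tied to the domain length in dispersal units
    return int(min(6000, max(1200, 400 * L / b)))


def dominant_eigenvalue(
    kernel: DispersalKernel, r: float, domain: Domain, nodes: int | None = None
) -> float:
    """Dominant eigenvalue of N(x) -> r int k(x, y) N(y) dy on the domain.

    Nystrom discretization with Gauss-Legendre points (density tied to the
    domain length unless ``nodes`` is given); the kernel is symmetric, so
    the weighted matrix is symmetrized and its largest eigenvalue (real
    and positive by Perron-Frobenius) extracted by a Lanczos solve.
    """
    if nodes is None:
        nodes = _default_nodes(domain.L, kernel.b)
    if nodes < 2:
        raise ValueError("need at least 2 quadrature nodes")
    x, w = leggauss(nodes)
    a = domain.half
    x = x * a
    w = w * a
    K = r * kernel.density(x[:, None] - x[None, :])
    sw = np.sqrt(w)
    M = sw[:, None] * K * sw[None, :]
    lam = eigsh(M, k=1, which="LA", return_eigenvectors=False, tol=1e-12)
    return float(lam[0])


def ide_critical_length(kernel: DispersalKernel, r: float, nodes: int | None = None) -> float:
    """Deterministic critical domain length L* of the linear growth model.

    Smallest L for which the dominant eigenvalue of the discretized
    operator r int k(x,y) . dy on [-L/2, L/2] reaches 1; below L* the only
    steady state is extinction.  Requires r > 1.
    """
    if r <= 1.0:
        raise ValueError("no finite critical length exists for growth rate r <= 1")

    def g(L):
        return dominant_eigenvalue(kernel, r, Domain(L), nodes=nodes) - 1.0

    lo, hi = 1e-6 * kernel.b, 4.0 * kernel.b
    while g(hi) < 0.0:
        hi *= 2.0
        if hi > 1e4 * kernel.b:  # pragma: no cover
            raise RuntimeError("failed to bracket the critical length")
    return float(brentq(g, lo, hi, xtol=1e-7))


def laplace_critical_length_analytic(r: float, b: float = 1.0) -> float:
    """Closed-form L* for the Laplace kernel from its dispersion relation.

    The eigenvalue condition reduces to tan(sqrt(r-1) L / (2b)) =
    1/sqrt(r-1), hence L* = (2b/sqrt(r-1)) arctan(1/sqrt(r-1)).
    """
    if r <= 1.0:
        raise ValueError("no finite critical length exists for growth rate r <= 1")
    q = np.sqrt(r - 1.0)
    return float(2.0 * b / q * np.arctan(1.0 / q))
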