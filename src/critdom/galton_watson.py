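"""Dispersal-modified Galton-Watson branching processes.

A lineage reproduces according to a finite offspring pmf ``{p_i}`` with
generating function ``f`` and then every offspring independently settles
outside the habitat (and is lost) with probability ``F``.  Reproduction
happens first, dispersal second, so the probability of extinction of one
lineage by generation n satisfies

    d_n = f((1 - F) d_{n-1} + F),    d_0 = 0,

and the ultimate extinction probability d is the smallest fixed point of
that map in [0, 1].  Equivalently, the process is a classical Galton-Watson
process on the binomially thinned offspring law; both routes are exposed
here and must agree.  The effective mean offspring number is
``xi = E[r](1 - F)``, so the process is supercritical exactly when
``F < F* = 1 - 1/E[r]``.  Identifying ``1 - F`` with the modified dispersal
success ``S_hat(L)`` turns the criticality condition into a critical
domain length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import binom

from .dispersal import DispersalKernel, invert_modified_success
from .offspring import OffspringPMF

__all__ = [
    "ExtinctionSummary",
    "thinned_pmf",
    "mean_offspring",
    "extinction_by_generation",
    "ultimate_extinction",
    "extinction_for_population",
    "critical_retention",
    "critical_length",
    "domain_for_goal",
    "extinction_summary",
]

_FP_TOL = 1e-12


def _check_F(F: float) -> None:
    if not 0.0 <= F <= 1.0:
        raise ValueError("loss probability F must lie in [0, 1]")


def thinned_pmf(pmf: OffspringPMF, F: float) -> OffspringPMF:
    """Offspring law after binomial thinning by the loss probability F.

    Each of ``v`` offspring independently stays with probability ``1 - F``,
    so the probability of ``q`` settlers is
    ``p~_q = sum_{v>=q} C(v, q) p_v (1-F)^q F^(v-q)``.
    """
    _check_F(F)
    p = np.asarray(pmf.probs)
    v = np.arange(p.size)
    q = v[:, None]
    tilde = (binom.pmf(q, v[None, :], 1.0 - F) * p[None, :]).sum(axis=1)
    return OffspringPMF(tilde)


def mean_offspring(pmf: OffspringPMF, F: float) -> float:
    """Effective mean offspring number xi = E[r] (1 - F) after dispersal loss."""
    _check_F(F)
    return pmf.mean * (1.0 - F)


def extinction_by_generation(pmf: OffspringPMF, F: float, n: int) -> np.ndarray:
    """Cumulative extinction probabilities d_1..d_n of a single lineage.

    Iterates d_k = f((1-F) d_{k-1} + F) from d_0 = 0; the sequence is
    nondecreasing and converges to the ultimate extinction probability.
    """
    _check_F(F)
    if n < 1:
        raise ValueError("horizon n must be at least 1")
    d = np.empty(n)
    prev = 0.0
    for k in range(n):
        prev = float(pmf.pgf((1.0 - F) * prev + F))
        d[k] = prev
    return d


def ultimate_extinction(pmf: OffspringPMF, F: float = 0.0) -> float:
    """Smallest root in [0, 1] of d = f((1-F) d + F).

    Subcritical or critical processes (``E[r](1-F) <= 1``) go extinct
    almost surely and return exactly 1.  Otherwise monotone fixed-point
    iteration from 0 converges to the smallest root.
    """
    _check_F(F)
    if mean_offspring(pmf, F) <= 1.0:
        # trivial exception: every individual leaves exactly one settler
        if F == 0.0 and len(pmf.probs) > 1 and pmf.probs[1] == 1.0:
            return 0.0
        return 1.0
    d = 0.0
    for _ in range(100_000):
        nxt = float(pmf.pgf((1.0 - F) * d + F))
        if abs(nxt - d) < _FP_TOL:
            return nxt
        d = nxt
    return d  # pragma: no cover - geometric convergence reaches tolerance


def extinction_for_population(d: float, z: int) -> float:
    """Extinction probability d^z of z independent founding lineages."""
    if z < 1:
        raise ValueError("initial population z must be at least 1")
    if not 0.0 <= d <= 1.0:
        raise ValueError("d must be a probability")
    return float(d**z)


def critical_retention(pmf: OffspringPMF) -> float:
    """Critical loss fraction F* = max(0, 1 - 1/E[r]).

    For F < F* the modified process is supercritical; for F >= F*
    extinction is certain.
    """
    xi = pmf.mean
    if xi <= 1.0:
        return 0.0
    return 1.0 - 1.0 / xi


def critical_length(pmf: OffspringPMF, kernel: DispersalKernel) -> float:
    """Critical domain length: solve S_hat(L) = 1/E[r] for L."""
    xi = pmf.mean
    if xi <= 1.0:
        raise ValueError("no finite critical length: mean offspring number <= 1")
    return invert_modified_success(kernel, 1.0 / xi)


def domain_for_goal(
    pmf: OffspringPMF, kernel: DispersalKernel, z: int, goal: float
) -> tuple[float, float, float]:
    """Loss fraction and domain length achieving an extinction-risk goal.

    For ``z`` independent founders and a tolerated ultimate extinction
    probability ``goal``, the per-lineage requirement is
    ``d = goal^(1/z)``; solving ``d = f((1-F) d + F)`` for F and then
    ``S_hat(L) = 1 - F`` for L gives the smallest sufficient domain.

    Returns ``(d_required, F, L)``.
    """
    if z < 1:
        raise ValueError("initial population z must be at least 1")
    if not 0.0 < goal < 1.0:
        raise ValueError("goal must lie strictly between 0 and 1")
    d_req = goal ** (1.0 / z)
    d_min = ultimate_extinction(pmf, 0.0)
    if d_req <= d_min:
        raise ValueError(
            f"goal infeasible: even without dispersal loss the per-lineage "
            f"extinction probability is {d_min:.6g} (population bound "
            f"{d_min**z:.3g}), above the requested {d_req:.6g}"
        )

    def g(F):
        return float(pmf.pgf((1.0 - F) * d_req + F)) - d_req

    # g is increasing in F, negative at F=0 (d_req above the smallest root)
    # and 1 - d_req > 0 at F=1.
    F = float(brentq(g, 0.0, 1.0, xtol=1e-14))
    L = invert_modified_success(kernel, 1.0 - F)
    return d_req, F, L


@dataclass(frozen=True)
class ExtinctionSummary:
    """Finite-horizon and ultimate extinction probabilities of a lineage.

    ``d_z`` is the ultimate extinction probability of ``z`` independent
    founding lineages, ``d_ultimate ** z``.
    """

    d_by_generation: np.ndarray
    d_ultimate: float
    z: int
    d_z: float


def extinction_summary(pmf: OffspringPMF, F: float, n: int, z: int = 1) -> ExtinctionSummary:
    """Bundle d_1..d_n, the ultimate d, and the population-level d^z."""
    d_n = extinction_by_generation(pmf, F, n)
    d = ultimate_extinction(pmf, F)
    return ExtinctionSummary(
        d_by_generation=d_n, d_ultimate=d, z=z, d_z=extinction_for_population(d, z)
    )
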