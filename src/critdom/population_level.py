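"""Spatially implicit population-level approximation.

The total population follows the random recursion

    N_{n} = A_bar * r_bar * N_{n-1},

where, by the Central Limit Theorem applied to a population of size N,
the per-capita growth rate r_bar is approximately Normal(xi, sigma_r^2/N)
and the retained proportion A_bar approximately Normal(S_hat,
sigma_Shat^2/N).  Negative growth draws are censored to zero and
retention draws are clipped into [0, 1].  The population is real-valued;
extinction means first passage below a quasi-extinction threshold
(default 1).

A composite variant draws a single growth factor B_bar ~ Normal(E[B],
sigma_B^2/N) per generation, which is the form used for the
time-to-extinction experiment (mean extinction time grows linearly in
ln N_0 for a subcritical mean).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .dispersal import DispersalSuccess
from .offspring import EnvironmentEnsemble, OffspringPMF

__all__ = [
    "GrowthMoments",
    "Trajectory",
    "draw_per_capita_growth",
    "draw_retention",
    "simulate_population_level",
    "simulate_composite",
    "extinction_curve_population_level",
    "mean_time_to_extinction",
]

@dataclass(frozen=True)
class GrowthMoments:
    """Per-environment growth moments without an explicit offspring pmf.

    Useful for moment-level experiments, e.g. switching off demographic
    variance (all ``variances`` zero) while keeping environment-driven
    variation in the means.  Duck-types as an environment ensemble for the
    population-level draws.
    """

    means: tuple[float, ...]
    variances: tuple[float, ...]
    h: tuple[float, ...]

    def __post_init__(self) -> None:
        if not len(self.means) == len(self.variances) == len(self.h):
            raise ValueError("means, variances and h must have equal lengths")
        if abs(sum(self.h) - 1.0) > 1e-9:
            raise ValueError("state probabilities must sum to 1")

    @property
    def state_means(self) -> np.ndarray:
        return np.asarray(self.means)

    @property
    def state_variances(self) -> np.ndarray:
        return np.asarray(self.variances)

    def sample_state(self, rng: np.random.Generator, size=None):
        return rng.choice(len(self.h), size=size, p=np.asarray(self.h))


ReproductiveLaw = Union[OffspringPMF, EnvironmentEnsemble, GrowthMoments]


@dataclass(frozen=True)
class Trajectory:
    """Population sizes N_0..N_T and the first-passage extinction time."""

    sizes: np.ndarray
    extinction_generation: Optional[int]


def _censor(draws: np.ndarray, truncate: bool, rng: np.random.Generator,
            mean: float, sd: np.ndarray) -> np.ndarray:
    """Map negative normal draws to zero (censor) or redraw (truncate)."""
    if not truncate:
        return np.maximum(draws, 0.0)
    bad = draws < 0.0
    while np.any(bad):
        draws = np.where(bad, rng.normal(mean, sd), draws)
        bad = draws < 0.0
    return draws


def draw_per_capita_growth(
    law: ReproductiveLaw,
    N,
    rng: np.random.Generator,
    truncate: bool = False,
):
    """Draw the population-averaged per-capita growth rate r_bar.

    Normal(xi, sigma_r^2/N) censored at zero (default) or truncated and
    redrawn.  Under an environment ensemble, one state is drawn first and
    its (xi^j, Var^j) used.
    """
    N = np.asarray(N, dtype=float)
    if np.any(N <= 0):
        raise ValueError("population size must be positive to draw a growth rate")
    if isinstance(law, OffspringPMF):
        mean, var = law.mean, law.variance
        means = np.broadcast_to(mean, N.shape)
        sds = np.sqrt(var / N)
    else:
        j = law.sample_state(rng, size=N.shape if N.ndim else None)
        means = law.state_means[j]
        sds = np.sqrt(law.state_variances[j] / N)
    draws = rng.normal(means, sds)
    out = _censor(np.asarray(draws, dtype=float), truncate, rng, means, sds)
    return out if out.ndim else float(out)


def draw_retention(success: DispersalSuccess, N, rng: np.random.Generator):
    """Draw the retained proportion A_bar ~ Normal(S_hat, sigma_Shat^2/N), clipped to [0,1].

    ``sigma_Shat^2`` is the variance integral ``var_S_hat`` carried by the
    summary (the integral of (s^2/S - S_hat)^2 over the domain, without a
    1/L factor), scaled down by the population size N.
    """
    N = np.asarray(N, dtype=float)
    if np.any(N <= 0):
        raise ValueError("population size must be positive to draw retention")
    var = success.var_S_hat
    draws = rng.normal(success.S_hat, np.sqrt(var / N))
    out = np.clip(draws, 0.0, 1.0)
    return out if out.ndim else float(out)


def simulate_population_level(
    law: ReproductiveLaw,
    success: DispersalSuccess,
    N0: float,
    max_generations: int,
    rng: np.random.Generator,
    threshold: float = 1.0,
    truncate: bool = False,
) -> Trajectory:
    """Iterate N_n = A_bar r_bar N_{n-1} until quasi-extinction or the horizon."""
    if threshold <= 0:
        raise ValueError("quasi-extinction threshold must be positive")
    sizes = [float(N0)]
    if N0 < threshold:
        return Trajectory(sizes=np.array(sizes), extinction_generation=0)
    N = float(N0)
    for gen in range(1, max_generations + 1):
        r = draw_per_capita_growth(law, N, rng, truncate=truncate)
        A = draw_retention(success, N, rng)
        N = A * r * N
        sizes.append(N)
        if N < threshold:
            return Trajectory(sizes=np.array(sizes), extinction_generation=gen)
    return Trajectory(sizes=np.array(sizes), extinction_generation=None)


def simulate_composite(
    B_mean: float,
    B_var: float,
    N0: float,
    max_generations: int,
    rng: np.random.Generator,
    threshold: float = 1.0,
    scale_variance: bool = True,
) -> Trajectory:
    """Single composite growth factor B_bar ~ Normal(E[B], sigma_B^2 / N) per step.

    ``scale_variance=False`` uses a constant variance sigma_B^2 instead of
    the CLT 1/N scaling.
    """
    if B_mean < 0 or B_var < 0:
        raise ValueError("composite growth mean and variance must be nonnegative")
    sizes = [float(N0)]
    if N0 < threshold:
        return Trajectory(sizes=np.array(sizes), extinction_generation=0)
    N = float(N0)
    for gen in range(1, max_generations + 1):
        var = B_var / N if scale_variance else B_var
        B = max(rng.normal(B_mean, np.sqrt(var)), 0.0)
        N = B * N
        sizes.append(N)
        if N < threshold:
            return Trajectory(sizes=np.array(sizes), extinction_generation=gen)
    return Trajectory(sizes=np.array(sizes), extinction_generation=None)


def extinction_curve_population_level(
    law: ReproductiveLaw,
    success: DispersalSuccess,
    N0: float,
    generations: int,
    replicates: int,
    seed: int,
    threshold: float = 1.0,
    truncate: bool = False,
) -> np.ndarray:
    """Vectorized cumulative quasi-extinction probabilities over replicates.

    All replicates advance together; returns the fraction extinct
    (first passage below the threshold) by each generation 1..n.
    """
    rng = np.random.default_rng(seed)
    N = np.full(replicates, float(N0))
    extinct_at = np.full(replicates, np.iinfo(np.int64).max, dtype=np.int64)
    active = N >= threshold
    extinct_at[~active] = 0
    curve = np.empty(generations)
    for gen in range(1, generations + 1):
        idx = np.flatnonzero(active)
        if idx.size:
            Na = N[idx]
            r = draw_per_capita_growth(law, Na, rng, truncate=truncate)
            A = draw_retention(success, Na, rng)
            Na = A * r * Na
            N[idx] = Na
            died = Na < threshold
            extinct_at[idx[died]] = gen
            active[idx[died]] = False
        curve[gen - 1] = np.mean(extinct_at <= gen)
    return curve


def mean_time_to_extinction(
    B_mean: float,
    B_var: float,
    N0_grid,
    replicates: int,
    seed: int,
    max_generations: int = 10_000,
    threshold: float = 1.0,
    scale_variance: bool = True,
) -> pd.DataFrame:
    """Monte-Carlo mean first-passage time below the threshold per N0.

    Returns a DataFrame with columns ``N0``, ``mean_time``, ``se``; for a
    subcritical mean (E[B] < 1) the mean time grows linearly in ln(N0).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for N0 in N0_grid:
        N = np.full(replicates, float(N0))
        t = np.zeros(replicates, dtype=np.int64)
        active = N >= threshold
        t[~active] = 0
        for gen in range(1, max_generations + 1):
            idx = np.flatnonzero(active)
            if idx.size == 0:
                break
            Na = N[idx]
            var = B_var / Na if scale_variance else np.full_like(Na, B_var)
            B = np.maximum(rng.normal(B_mean, np.sqrt(var)), 0.0)
            Na = B * Na
            N[idx] = Na
            died = Na < threshold
            t[idx[died]] = gen
            active[idx[died]] = False
        times = t[~active]  # replicates that reached extinction
        rows.append(
            {
                "N0": float(N0),
                "mean_time": float(times.mean()) if times.size else float("nan"),
                "se": float(times.std(ddof=1) / np.sqrt(times.size))
                if times.size > 1
                else float("nan"),
                "extinct_fraction": float(times.size / replicates),
            }
        )
    return pd.DataFrame(rows)
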