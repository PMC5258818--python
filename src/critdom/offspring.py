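"""Offspring laws and environment ensembles.

The reproductive law of a single individual is a finite probability mass
function ``{p_i}``: ``p_i`` is the probability of leaving ``i`` (female)
offspring in one generation, with parental survival folded into the
offspring count.  Environmental stochasticity is modelled as an iid draw,
each generation, of one state from a finite ensemble; every individual
alive in that generation reproduces according to the drawn state's pmf.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["OffspringPMF", "EnvironmentState", "EnvironmentEnsemble"]

_ATOL = 1e-12


@dataclass(frozen=True)
class OffspringPMF:
    """Finite offspring probability mass function ``{p_0, ..., p_imax}``.

    Parameters
    ----------
    probs
        Probabilities of producing ``0, 1, ..., imax`` offspring.  Must be
        nonnegative and sum to 1 (within 1e-12).
    """

    probs: tuple[float, ...]

    def __init__(self, probs) -> None:
        p = np.asarray(probs, dtype=float)
        if p.ndim != 1 or p.size == 0:
            raise ValueError("offspring pmf must be a non-empty 1-D vector")
        if np.any(p < 0):
            raise ValueError("offspring probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"offspring probabilities sum to {p.sum()}, not 1")
        object.__setattr__(self, "probs", tuple(p / p.sum()))

    @property
    def support(self) -> np.ndarray:
        return np.arange(len(self.probs))

    @property
    def mean(self) -> float:
        """Mean offspring number xi = E[r] = f'(1)."""
        return float(np.dot(self.support, self.probs))

    @property
    def variance(self) -> float:
        """Offspring-number variance sigma_r^2."""
        p = np.asarray(self.probs)
        i = self.support
        return float(np.dot(i * i, p) - self.mean**2)

    def pgf(self, s):
        """Probability generating function f(s) = sum_i p_i s^i."""
        s = np.asarray(s, dtype=float)
        # Horner evaluation; exact for the finite support.
        out = np.zeros_like(s)
        for p in reversed(self.probs):
            out = out * s + p
        return out if out.ndim else float(out)

    def pgf_prime(self, s):
        """Derivative f'(s) of the generating function."""
        s = np.asarray(s, dtype=float)
        out = np.zeros_like(s)
        for i in range(len(self.probs) - 1, 0, -1):
            out = out * s + i * self.probs[i]
        return out if out.ndim else float(out)

    def sample(self, rng: np.random.Generator, size=None):
        """Draw iid offspring counts."""
        return rng.choice(len(self.probs), size=size, p=np.asarray(self.probs))


@dataclass(frozen=True)
class EnvironmentState:
    """One environmental state: label, occurrence probability, offspring pmf."""

    label: str
    h: float
    pmf: OffspringPMF


@dataclass(frozen=True)
class EnvironmentEnsemble:
    """Finite ensemble of iid environmental states.

    Each generation, one state is drawn with probability ``h_j`` and its
    offspring pmf applies to every individual alive that generation.
    """

    states: tuple[EnvironmentState, ...] = field()

    def __init__(self, states) -> None:
        states = tuple(states)
        if not states:
            raise ValueError("ensemble needs at least one state")
        h = np.array([s.h for s in states], dtype=float)
        if np.any(h < 0):
            raise ValueError("state probabilities must be nonnegative")
        if abs(h.sum() - 1.0) > 1e-9:
            raise ValueError(f"state probabilities sum to {h.sum()}, not 1")
        object.__setattr__(self, "states", states)

    @classmethod
    def from_pairs(cls, pairs) -> "EnvironmentEnsemble":
        """Build from ``[(h, probs), ...]`` pairs."""
        return cls(
            EnvironmentState(label=f"state_{j + 1}", h=float(h), pmf=OffspringPMF(p))
            for j, (h, p) in enumerate(pairs)
        )

    @property
    def h(self) -> np.ndarray:
        return np.array([s.h for s in self.states])

    @property
    def state_means(self) -> np.ndarray:
        """Per-state mean offspring numbers xi^j."""
        return np.array([s.pmf.mean for s in self.states])

    @property
    def state_variances(self) -> np.ndarray:
        return np.array([s.pmf.variance for s in self.states])

    @property
    def mean(self) -> float:
        """Ensemble-averaged mean offspring number sum_j h_j xi^j."""
        return float(np.dot(self.h, self.state_means))

    def sample_state(self, rng: np.random.Generator, size=None):
        """Draw environment indices for one or more generations."""
        return rng.choice(len(self.states), size=size, p=self.h)
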