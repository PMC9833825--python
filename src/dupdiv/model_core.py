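"""Genotype space and the expression-to-fitness map.

The unit of evolution is a tandem array at a reporter locus: a genotype is
``(k, m)`` where ``k`` is the number of tandem copies of the locus and ``m``
of those copies carry an adaptive promoter allele.  Two mutation routes can
raise expression of the locus: increasing dosage (``k``) or strengthening the
promoter of individual copies (``m``).

Fitness follows a saturating expression-demand map: growth rate rises
linearly with total expression up to a demand level ``D`` and plateaus there,
minus a per-extra-copy cost.  Past the plateau extra expression is worthless,
which makes copy-number and point mutations negatively epistatic whenever
either alone satisfies demand — the mechanism behind "amplification
hindrance" of point-mutation fixation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Genotype",
    "AlleleParams",
    "Environment",
    "MutationRates",
    "expression_level",
    "growth_rate_of",
    "expression_grid",
    "growth_rate_grid",
]


@dataclass(frozen=True)
class Genotype:
    """A tandem-array state: ``k`` copies, ``m`` of them promoter-mutant.

    The ancestral genotype is ``(k=1, m=0)``.  A combination mutant carries
    both an amplification and at least one mutant copy (``k >= 2, m >= 1``).
    """

    k: int
    m: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"copy count k must be >= 1, got {self.k}")
        if not 0 <= self.m <= self.k:
            raise ValueError(f"mutant copies m must satisfy 0 <= m <= k, got m={self.m}, k={self.k}")

    @property
    def is_ancestral(self) -> bool:
        return self.k == 1 and self.m == 0

    @property
    def is_amplified(self) -> bool:
        return self.k >= 2

    @property
    def is_combination(self) -> bool:
        return self.k >= 2 and self.m >= 1


@dataclass(frozen=True)
class AlleleParams:
    """Per-copy expression strengths of the two promoter alleles.

    ``beta_anc`` is the leaky baseline expression of the random ancestral
    promoter sequence; ``beta_mut`` is the expression of the evolved
    (point-mutant) promoter.  Units are arbitrary expression units; the
    defaults put one mutant copy at 20x a single ancestral copy.
    """

    beta_anc: float = 1.0
    beta_mut: float = 20.0

    def __post_init__(self) -> None:
        if not 0 < self.beta_anc < self.beta_mut:
            raise ValueError(
                f"require 0 < beta_anc < beta_mut, got beta_anc={self.beta_anc}, beta_mut={self.beta_mut}"
            )


@dataclass(frozen=True)
class Environment:
    """Expression demand and the growth-rate scale it maps onto.

    Parameters
    ----------
    demand
        Expression level at which growth saturates (expression units).  Low
        demand is satisfiable by either mutation route alone; high demand
        needs both.
    r0
        Growth rate at zero expression (per hour).  Cells grow without any
        locus expression, so r0 > 0 by default.
    rmax
        Growth rate at or above demand (per hour).
    cost_per_copy
        Growth-rate penalty per extra tandem copy beyond the first
        (per hour per copy).
    """

    demand: float
    r0: float = 0.2
    rmax: float = 0.9
    cost_per_copy: float = 0.01

    def __post_init__(self) -> None:
        if self.demand <= 0:
            raise ValueError("demand must be > 0")
        if not self.rmax > self.r0 >= 0:
            raise ValueError("require rmax > r0 >= 0")
        if self.cost_per_copy < 0:
            raise ValueError("cost_per_copy must be >= 0")


@dataclass(frozen=True)
class MutationRates:
    """Per-cell-per-generation rates of the three mutation processes.

    ``mu_dup``: single copy -> tandem duplication.  ``mu_step``: per-junction
    amplification/deletion step rate, applying only once a duplication exists
    (k >= 2) and scaling with the junction count (k - 1).  ``mu_pm``:
    adaptive point mutation, per gene copy (so a class with k - m ancestral
    copies mutates at mu_pm * (k - m)).
    """

    mu_dup: float = 1e-3
    mu_step: float = 1e-2
    mu_pm: float = 1e-7

    def __post_init__(self) -> None:
        for name in ("mu_dup", "mu_step", "mu_pm"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1), got {v}")


def expression_level(g: Genotype, a: AlleleParams) -> float:
    """Total expression of the array: ``(k - m) * beta_anc + m * beta_mut``.

    Strictly increasing in both k and m (since beta_mut > beta_anc > 0).
    """
    return (g.k - g.m) * a.beta_anc + g.m * a.beta_mut


def growth_rate_of(g: Genotype, env: Environment, a: AlleleParams) -> float:
    """Growth rate of a genotype: saturating benefit minus copy cost.

    r = r0 + (rmax - r0) * min(E / D, 1) - cost * (k - 1), clamped at 0.

    The hard plateau at E = D is what makes a point mutation worthless in an
    already-amplified background (negative epistasis): once expression meets
    demand, extra expression buys nothing while extra copies still cost.
    """
    e = expression_level(g, a)
    r = env.r0 + (env.rmax - env.r0) * min(e / env.demand, 1.0) - env.cost_per_copy * (g.k - 1)
    return max(r, 0.0)


def expression_grid(kmax: int, a: AlleleParams) -> np.ndarray:
    """Expression for every class, as a (kmax, kmax+1) array indexed [k-1, m].

    Cells with m > k are unreachable; they are filled with NaN.
    """
    k = np.arange(1, kmax + 1)[:, None]
    m = np.arange(0, kmax + 1)[None, :]
    e = (k - m) * a.beta_anc + m * a.beta_mut
    return np.where(m <= k, e, np.nan)


def growth_rate_grid(kmax: int, env: Environment, a: AlleleParams) -> np.ndarray:
    """Growth rate for every class (kmax, kmax+1), [k-1, m]; 0 where m > k."""
    k = np.arange(1, kmax + 1)[:, None]
    m = np.arange(0, kmax + 1)[None, :]
    e = (k - m) * a.beta_anc + m * a.beta_mut
    r = env.r0 + (env.rmax - env.r0) * np.minimum(e / env.demand, 1.0) - env.cost_per_copy * (k - 1)
    r = np.clip(r, 0.0, None)
    return np.where(m <= k, r, 0.0)
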