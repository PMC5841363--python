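"""Core model types and payoff/fitness formulas.

The model: a well-mixed population of ``N`` haploid individuals. Each
individual carries a *capacitor* of potentially expressible phenotypes,
expresses exactly one of them, and plays a public goods game (PGG) only with
individuals expressing the same phenotype. The expressed phenotype is the
only observable tag, so it acts as an assortment device (a green-beard-like
signal). Carrying a capacitor of volume ``K`` costs ``theta * K`` per payoff
accounting period, which makes phenotypic diversity itself an evolvable,
costly trait.

Capacitors are *nested*: a capacitor of volume ``K`` contains phenotypes
``{1, ..., K}``. This is the convention under which a mutant of volume
``K_Y`` matches the resident's phenotype with probability ``1/K_Y`` (random
phenotype switching), and a smaller capacitor ``K_Y < K_X`` covers the
resident's expressed phenotype with probability ``K_Y / K_X``.

Payoffs here are *expected* payoffs: the PGG group of size ``g`` is drawn
uniformly (without replacement) from the focal individual's subpopulation,
and the formulas average over the group composition. The number of games an
individual accrues scales with its subpopulation size ``n`` through the
interaction-rate function ``chi(n) = chi_slope * n``; a subpopulation smaller
than ``g`` plays no games at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

__all__ = [
    "ModelParams",
    "Strain",
    "Individual",
    "PairwisePayoffs",
    "payoff_same_phenotype",
    "payoff_diff_phenotype",
    "fitness",
    "COOPERATOR",
    "DEFECTOR",
]

COOPERATOR = 1
DEFECTOR = 0


@dataclass(frozen=True)
class ModelParams:
    """All scalar parameters of the model.

    Parameters
    ----------
    N : int
        Population size (constant throughout the Moran process).
    r : float
        Synergy factor of the public goods game; the pot is multiplied by
        ``r`` before being split among the ``g`` group members. The social
        dilemma requires ``1 < r < g``.
    g : int
        PGG group size. A subpopulation must reach at least ``g`` members
        for any game to take place in it.
    c : float
        Contribution of a cooperator per game (default 1).
    beta : float
        Intensity of selection; fitness is ``exp(beta * payoff)``.
    theta : float
        Cost rate per capacitor slot: an individual of volume ``K`` pays
        ``theta * K``.
    mu : float
        Mutation probability per reproduction event (only used by the
        agent-based simulator; the embedded chain works in the rare-mutation
        limit).
    M : int
        Largest allowed capacitor volume; there are ``2 * M`` strains.
    chi_slope : float
        Slope of the linear interaction-rate function ``chi(x) = slope * x``,
        which sets the time scale of game interaction relative to selection.
    """

    N: int = 40
    r: float = 3.2
    g: int = 5
    c: float = 1.0
    beta: float = 0.1
    theta: float = 0.12
    mu: float = 0.01
    M: int = 50
    chi_slope: float = 0.1

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError(f"N must be >= 2, got {self.N}")
        if not (1.0 < self.r < self.g):
            raise ValueError(
                f"synergy factor must satisfy 1 < r < g, got r={self.r}, g={self.g}"
            )
        if self.g > self.N:
            raise ValueError(f"group size g={self.g} exceeds population size N={self.N}")
        if self.c <= 0:
            raise ValueError(f"cooperation cost c must be positive, got {self.c}")
        if self.beta < 0:
            raise ValueError(f"selection intensity beta must be >= 0, got {self.beta}")
        if self.theta < 0:
            raise ValueError(f"phenotype cost rate theta must be >= 0, got {self.theta}")
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError(f"mutation rate mu must lie in [0, 1], got {self.mu}")
        if self.M < 1:
            raise ValueError(f"maximum capacitor volume M must be >= 1, got {self.M}")
        if self.chi_slope < 0:
            raise ValueError(f"chi_slope must be >= 0, got {self.chi_slope}")

    def chi(self, x: float) -> float:
        """Interaction rate of a subpopulation of size ``x``."""
        return self.chi_slope * x


@dataclass(frozen=True, order=True)
class Strain:
    """A (strategy, capacitor-volume) class; the unit of the embedded chain."""

    strategy: int
    K: int

    def validate(self, M: int) -> None:
        if self.strategy not in (COOPERATOR, DEFECTOR):
            raise ValueError(f"strategy must be 0 (D) or 1 (C), got {self.strategy}")
        if not (1 <= self.K <= M):
            raise ValueError(f"capacitor volume must lie in [1, {M}], got {self.K}")

    @property
    def label(self) -> str:
        return f"{'C' if self.strategy == COOPERATOR else 'D'}{self.K}"


@dataclass(frozen=True)
class Individual:
    """A (phenotype, strategy, capacitor-volume) triplet; the unit of the ABM.

    Under the nested-capacitor convention the expressed phenotype is an
    integer in ``[1, K]``.
    """

    phenotype: int
    strategy: int
    K: int

    def __post_init__(self) -> None:
        if not (1 <= self.phenotype <= self.K):
            raise ValueError(
                f"expressed phenotype {self.phenotype} outside capacitor [1, {self.K}]"
            )


class PairwisePayoffs(NamedTuple):
    """Expected payoffs of a focal mutant (A) and a resident (B)."""

    P_A: float
    P_B: float


def _check_mutant_count(i: int, N: int) -> None:
    if not (1 <= i <= N - 1):
        raise ValueError(f"mutant count i must lie in [1, {N - 1}], got {i}")


def payoff_same_phenotype(
    i: int, S_A: int, S_B: int, K_A: int, K_B: int, params: ModelParams
) -> PairwisePayoffs:
    """Expected payoffs when mutants and residents share one phenotype.

    With both types in the same subpopulation (here the whole population of
    size ``N``, with ``i`` mutants), every individual plays ``chi(N)`` games
    on average, each in a group of ``g`` drawn uniformly from the remaining
    ``N - 1`` individuals. Averaging the PGG payoff over the hypergeometric
    group composition gives, for a mutant A,

        P_A = chi(N) * c * { (r/g) * [ (1 + (g-1)(i-1)/(N-1)) * S_A
                                       + (g-1 - (g-1)(i-1)/(N-1)) * S_B ]
                             - S_A }  -  theta * K_A

    and the mirror-image expression for a resident B. The capacitor cost is
    paid regardless of game participation.
    """
    _check_mutant_count(i, params.N)
    _validate_pair(S_A, S_B, K_A, K_B, params.M)
    N, r, g, c = params.N, params.r, params.g, params.c
    chi_N = params.chi(N)
    # expected number of co-players of the mutant type, conditioned on focal
    others_A = (g - 1) * (i - 1) / (N - 1)
    others_B = (g - 1) * i / (N - 1)
    P_A = chi_N * c * ((r / g) * ((1 + others_A) * S_A + (g - 1 - others_A) * S_B) - S_A)
    P_B = chi_N * c * ((r / g) * (others_B * S_A + (g - others_B) * S_B) - S_B)
    return PairwisePayoffs(P_A - params.theta * K_A, P_B - params.theta * K_B)


def payoff_diff_phenotype(
    i: int, S_A: int, S_B: int, K_A: int, K_B: int, params: ModelParams
) -> PairwisePayoffs:
    """Expected payoffs when mutants and residents express distinct phenotypes.

    The two types then sit in separate subpopulations of sizes ``i`` and
    ``N - i``; games only happen within each, and only if the subpopulation
    reaches the group size ``g``. A pure subpopulation of cooperators earns
    ``(r - 1) * c`` per game; defectors among themselves earn nothing:

        P_A = chi(i)     * (r - 1) * c * S_A * [i >= g]      - theta * K_A
        P_B = chi(N - i) * (r - 1) * c * S_B * [N - i >= g]  - theta * K_B
    """
    _check_mutant_count(i, params.N)
    _validate_pair(S_A, S_B, K_A, K_B, params.M)
    N, r, c = params.N, params.r, params.c
    game_A = params.chi(i) * (r - 1) * c * S_A if i >= params.g else 0.0
    game_B = params.chi(N - i) * (r - 1) * c * S_B if N - i >= params.g else 0.0
    return PairwisePayoffs(game_A - params.theta * K_A, game_B - params.theta * K_B)


def _validate_pair(S_A: int, S_B: int, K_A: int, K_B: int, M: int) -> None:
    Strain(S_A, K_A).validate(M)
    Strain(S_B, K_B).validate(M)


def fitness(payoff: float, beta: float) -> float:
    """Exponential payoff-to-fitness map ``f = exp(beta * payoff)``.

    Strictly positive; equals 1 under neutral selection (``beta = 0``) or at
    zero payoff. Downstream code works with fitness *ratios* in log space, so
    this direct form is for inspection and small-scale use only.
    """
    if not math.isfinite(payoff):
        raise ValueError(f"payoff must be finite, got {payoff}")
    return math.exp(beta * payoff)
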