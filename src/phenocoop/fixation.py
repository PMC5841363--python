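"""Moran birth-death transition and fixation probabilities.

A single mutant strain competes with a monomorphic resident population under
frequency-dependent Moran updating: one individual reproduces with
probability proportional to fitness ``exp(beta * payoff)``, then one of the
``N`` incumbents (possibly the reproducer) dies uniformly at random. With
``i`` mutants the chain moves ``i -> i + 1`` with

    T_up(i)   = i * f_A / (i * f_A + (N - i) * g_B) * (N - i) / N

and ``i -> i - 1`` with the mirror expression; ``i = 0`` and ``i = N`` are
absorbing. Two payoff regimes exist, fixed for the whole sweep: either the
mutant expressed the resident's phenotype (one shared subpopulation) or a
different one (two subpopulations). Phenotype expression is heritable in the
absence of mutation, so the regime cannot flip mid-competition.

All products of fitness ratios are taken in log space: the classical ratio
``T_down(k) / T_up(k)`` equals ``exp(beta * (P_B(k) - P_A(k)))``, so the
fixation probability of a single mutant is

    phi_1 = 1 / (1 + sum_{l=1}^{N-1} exp(beta * sum_{k<=l} (P_B(k) - P_A(k))))

which never overflows regardless of ``beta`` or the interaction rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .model_core import (
    ModelParams,
    Strain,
    payoff_diff_phenotype,
    payoff_same_phenotype,
)

__all__ = [
    "FixationQuery",
    "step_probabilities",
    "fixation_probability",
    "payoff_gap_profile",
]


@dataclass(frozen=True)
class FixationQuery:
    """One mutant-vs-resident competition in a fixed phenotype regime."""

    mutant: Strain
    resident: Strain
    same_phenotype: bool
    params: ModelParams

    def __post_init__(self) -> None:
        self.mutant.validate(self.params.M)
        self.resident.validate(self.params.M)


def payoff_gap_profile(query: FixationQuery) -> np.ndarray:
    """``P_B(i) - P_A(i)`` (resident minus mutant) for ``i = 1 .. N-1``.

    Vectorized over the mutant count; this array is the only ingredient the
    fixation probability needs.
    """
    p = query.params
    N, r, g, c, theta = p.N, p.r, p.g, p.c, p.theta
    S_A, K_A = query.mutant.strategy, query.mutant.K
    S_B, K_B = query.resident.strategy, query.resident.K
    i = np.arange(1, N, dtype=np.float64)
    if query.same_phenotype:
        chi_N = p.chi(N)
        others_A = (g - 1) * (i - 1) / (N - 1)
        others_B = (g - 1) * i / (N - 1)
        P_A = chi_N * c * ((r / g) * ((1 + others_A) * S_A + (g - 1 - others_A) * S_B) - S_A)
        P_B = chi_N * c * ((r / g) * (others_B * S_A + (g - others_B) * S_B) - S_B)
    else:
        P_A = np.where(i >= g, p.chi(i) * (r - 1) * c * S_A, 0.0)
        P_B = np.where(N - i >= g, p.chi(N - i) * (r - 1) * c * S_B, 0.0)
    return (P_B - theta * K_B) - (P_A - theta * K_A)


def step_probabilities(i: int, query: FixationQuery) -> tuple[float, float, float]:
    """``(T_up, T_down, T_stay)`` of the Moran chain at mutant count ``i``.

    Computed from the payoff gap only, so large payoffs cannot overflow the
    fitness exponentials.
    """
    p = query.params
    N = p.N
    if not (1 <= i <= N - 1):
        raise ValueError(f"mutant count i must lie in [1, {N - 1}], got {i}")
    pay = payoff_same_phenotype if query.same_phenotype else payoff_diff_phenotype
    P_A, P_B = pay(
        i,
        query.mutant.strategy,
        query.resident.strategy,
        query.mutant.K,
        query.resident.K,
        p,
    )
    gap = p.beta * (P_B - P_A)  # log(g_B / f_A)
    # T_up = i f_A / (i f_A + (N-i) g_B) * (N-i)/N, stabilised via the gap
    if gap >= 0:
        w = np.exp(-gap)  # f_A / g_B <= 1
        T_up = (i * w) / (i * w + (N - i)) * (N - i) / N
        T_down = (N - i) / (i * w + (N - i)) * i / N
    else:
        w = np.exp(gap)  # g_B / f_A < 1
        T_up = i / (i + (N - i) * w) * (N - i) / N
        T_down = (N - i) * w / (i + (N - i) * w) * i / N
    return float(T_up), float(T_down), float(1.0 - T_up - T_down)


def fixation_probability(query: FixationQuery) -> float:
    """Probability that a single mutant takes over the resident population.

    Identical strains in the same regime drift neutrally and fix with
    probability exactly ``1 / N`` (the log-space sum is exactly zero term by
    term, so the neutral value is bit-stable).
    """
    beta = query.params.beta
    gaps = beta * payoff_gap_profile(query)
    # phi_1 = 1 / (1 + sum_l exp(cumsum_l)); include l = 0 term as exp(0)
    log_terms = np.concatenate(([0.0], np.cumsum(gaps)))
    return float(np.exp(-logsumexp(log_terms)))
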