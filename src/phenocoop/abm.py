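"""Agent-based frequency-dependent Moran simulator.

The embedded strain chain is exact only in the rare-mutation limit; this
module simulates the full individual-based process for any mutation rate
``mu``. Each of the ``N`` individuals carries a (phenotype, strategy,
capacitor-volume) triplet. Every Moran step:

1. payoffs are realized from the current subpopulation composition,
2. a parent is drawn with probability proportional to ``exp(beta * payoff)``,
3. a uniformly random incumbent (possibly the parent) dies and is replaced
   by the offspring,
4. with probability ``mu`` the offspring is a fresh mutant — uniform
   strategy, uniform volume ``K' in {1..M}``, uniform expressed phenotype in
   ``{1..K'}`` (random phenotype switching); otherwise it inherits the
   parent's full triplet, including the *expressed* phenotype.

Phenotype inheritance in the no-mutation branch is what lets the pairwise
same-/different-phenotype fixation structure of the analytic model emerge
from the simulation.

Two payoff realizations are available:

``sampled`` (default)
    Explicit public-goods games are drawn: a subpopulation of size
    ``n >= g`` holds ``chi(n) * n / g`` games per step (fractional counts
    rounded stochastically), each with ``g`` members drawn uniformly without
    replacement, so every member plays ``chi(n)`` games in expectation.
    Payoffs are the realized sums; their mean is exactly the expected-payoff
    formula below. This is the process the analytic machinery approximates,
    and the one used for finite-mutation study runs.

``expected``
    Each individual in a subpopulation of size ``n`` with ``j`` cooperators
    receives the composition-averaged payoff ``chi(n) * E[game] - theta*K``
    deterministically. This removes game-sampling noise and matches the
    payoff functions inside the analytic Moran transition probabilities
    term for term, which makes it the right mode for cross-checking the
    simulator against analytic fixation probabilities.

The hot loop is compiled with numba; at the default study size
(``N = 40``, ``M = 50``) it advances a few hundred thousand to a million
steps per second on one core, and seeded runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .model_core import ModelParams, Strain

__all__ = [
    "Population",
    "TrajectorySummary",
    "compute_payoffs",
    "moran_step",
    "run",
    "simulate_pairwise_fixation",
]

_COARSE = ("Low", "Middle", "High")
_MODE_EXPECTED = 0
_MODE_SAMPLED = 1


def _mode_code(payoff_mode: str) -> int:
    try:
        return {"expected": _MODE_EXPECTED, "sampled": _MODE_SAMPLED}[payoff_mode]
    except KeyError:
        raise ValueError(f"payoff_mode must be 'expected' or 'sampled', got {payoff_mode!r}")


@dataclass
class Population:
    """The N individuals of the simulator as parallel arrays.

    ``phenotype[i]`` lies in ``[1, K[i]]`` (nested capacitors); ``strategy``
    is 0/1; arrays always have length ``N``.
    """

    phenotype: np.ndarray
    strategy: np.ndarray
    K: np.ndarray
    step_count: int = 0

    def __post_init__(self) -> None:
        n = len(self.phenotype)
        if not (len(self.strategy) == len(self.K) == n):
            raise ValueError("population arrays must have equal length")
        if np.any(self.phenotype < 1) or np.any(self.phenotype > self.K):
            raise ValueError("expressed phenotype outside capacitor")

    @classmethod
    def random(cls, params: ModelParams, rng: np.random.Generator) -> "Population":
        """Uniformly random initial population (strain and phenotype)."""
        K = rng.integers(1, params.M + 1, size=params.N)
        strategy = rng.integers(0, 2, size=params.N)
        phenotype = rng.integers(1, K + 1)
        return cls(phenotype=phenotype, strategy=strategy, K=K)

    @classmethod
    def monomorphic(cls, strain: Strain, phenotype: int, params: ModelParams) -> "Population":
        strain.validate(params.M)
        N = params.N
        return cls(
            phenotype=np.full(N, phenotype, dtype=np.int64),
            strategy=np.full(N, strain.strategy, dtype=np.int64),
            K=np.full(N, strain.K, dtype=np.int64),
        )


@dataclass
class TrajectorySummary:
    """Time averages of a simulation run, measured after burn-in."""

    mean_cooperator_fraction: float
    mean_K_by_strategy: dict
    state_occupancy: dict
    n_steps: int
    burn_in: int
    seed: int
    params: ModelParams = field(repr=False, default=None)


@njit(cache=True)
def _expected_payoffs(phenotype, strategy, K, N, g, r, c, theta, chi_slope, M, out):
    cnt = np.zeros(M + 1, dtype=np.int64)
    coop = np.zeros(M + 1, dtype=np.int64)
    for idx in range(N):
        h = phenotype[idx]
        cnt[h] += 1
        coop[h] += strategy[idx]
    for idx in range(N):
        h = phenotype[idx]
        n = cnt[h]
        j = coop[h]
        if n < g:
            out[idx] = -theta * K[idx]
        else:
            if strategy[idx] == 1:
                game = (r / g) * c * (1.0 + (g - 1.0) * (j - 1.0) / (n - 1.0)) - c
            else:
                game = (r / g) * c * ((g - 1.0) * j / (n - 1.0))
            out[idx] = chi_slope * n * game - theta * K[idx]


@njit(cache=True)
def _sampled_payoffs(phenotype, strategy, K, N, g, r, c, theta, chi_slope, M, out, members):
    # chi(n) * n / g games of size g per subpopulation: each member then
    # participates in chi(n) games in expectation, matching the analytic
    # per-individual interaction rate.
    for idx in range(N):
        out[idx] = -theta * K[idx]
    for h in range(1, M + 1):
        nm = 0
        for idx in range(N):
            if phenotype[idx] == h:
                members[nm] = idx
                nm += 1
        if nm < g:
            continue
        games_f = chi_slope * nm * nm / g
        games = int(games_f)
        if np.random.random() < games_f - games:
            games += 1
        for _ in range(games):
            # partial Fisher-Yates: first g slots become the group
            n_coop = 0
            for t in range(g):
                pick = t + int(np.random.random() * (nm - t))
                if pick >= nm:
                    pick = nm - 1
                tmp = members[t]
                members[t] = members[pick]
                members[pick] = tmp
                n_coop += strategy[members[t]]
            share = r * n_coop * c / g
            for t in range(g):
                out[members[t]] += share - c * strategy[members[t]]


def compute_payoffs(pop: Population, params: ModelParams) -> np.ndarray:
    """Per-individual *expected* payoff from the current subpopulations."""
    out = np.empty(len(pop.phenotype))
    _expected_payoffs(
        pop.phenotype.astype(np.int64),
        pop.strategy.astype(np.int64),
        pop.K.astype(np.int64),
        len(pop.phenotype),
        params.g,
        params.r,
        params.c,
        params.theta,
        params.chi_slope,
        params.M,
        out,
    )
    return out


def moran_step(pop: Population, params: ModelParams, rng: np.random.Generator) -> Population:
    """Advance the population by one birth-death event, in place.

    Reference single-step implementation (expected-payoff mode) driven by a
    numpy Generator; the long-run driver `run` uses the compiled loop with
    identical update semantics.
    """
    N = params.N
    payoffs = compute_payoffs(pop, params)
    w = np.exp(params.beta * (payoffs - payoffs.max()))
    parent = rng.choice(N, p=w / w.sum())
    dead = rng.integers(N)
    if rng.random() < params.mu:
        s_new = int(rng.integers(2))
        k_new = int(rng.integers(1, params.M + 1))
        h_new = int(rng.integers(1, k_new + 1))
    else:
        s_new = int(pop.strategy[parent])
        k_new = int(pop.K[parent])
        h_new = int(pop.phenotype[parent])
    pop.strategy[dead] = s_new
    pop.K[dead] = k_new
    pop.phenotype[dead] = h_new
    pop.step_count += 1
    return pop


@njit(cache=True)
def _one_step(phenotype, strategy, K, payoffs, members, N, M, g, r, c, beta, theta, mu,
              chi_slope, mode):
    if mode == 0:
        _expected_payoffs(phenotype, strategy, K, N, g, r, c, theta, chi_slope, M, payoffs)
    else:
        _sampled_payoffs(phenotype, strategy, K, N, g, r, c, theta, chi_slope, M, payoffs,
                         members)
    pmax = payoffs[0]
    for idx in range(1, N):
        if payoffs[idx] > pmax:
            pmax = payoffs[idx]
    total = 0.0
    for idx in range(N):
        payoffs[idx] = np.exp(beta * (payoffs[idx] - pmax))
        total += payoffs[idx]
    u = np.random.random() * total
    parent = N - 1
    acc = 0.0
    for idx in range(N):
        acc += payoffs[idx]
        if u < acc:
            parent = idx
            break
    dead = int(np.random.random() * N)
    if dead == N:  # guard against the measure-zero edge of random()
        dead = N - 1
    if np.random.random() < mu:
        s_new = 1 if np.random.random() < 0.5 else 0
        k_new = 1 + int(np.random.random() * M)
        if k_new > M:
            k_new = M
        h_new = 1 + int(np.random.random() * k_new)
        if h_new > k_new:
            h_new = k_new
    else:
        s_new = strategy[parent]
        k_new = K[parent]
        h_new = phenotype[parent]
    strategy[dead] = s_new
    K[dead] = k_new
    phenotype[dead] = h_new


@njit(cache=True)
def _run_core(
    phenotype, strategy, K, N, M, g, r, c, beta, theta, mu, chi_slope,
    n_steps, burn_in, seed, thin, low_edge, middle_edge, mode,
):
    np.random.seed(seed)
    payoffs = np.empty(N)
    members = np.empty(N, dtype=np.int64)
    sum_coop = 0.0
    sum_K_C = 0.0
    n_K_C = 0
    sum_K_D = 0.0
    n_K_D = 0
    occ = np.zeros(6, dtype=np.int64)  # (C, D) x (Low, Middle, High)
    n_rows = n_steps // thin if thin > 0 else 0
    traj = np.zeros((n_rows, 5))
    row = 0
    seen = np.zeros(M + 1, dtype=np.int64)
    for step in range(n_steps):
        _one_step(phenotype, strategy, K, payoffs, members, N, M, g, r, c, beta, theta,
                  mu, chi_slope, mode)
        nc = 0
        kc = 0.0
        kd = 0.0
        for idx in range(N):
            if strategy[idx] == 1:
                nc += 1
                kc += K[idx]
            else:
                kd += K[idx]
        if step >= burn_in:
            sum_coop += nc / N
            if nc > 0:
                mean_kc = kc / nc
                sum_K_C += mean_kc
                n_K_C += 1
                band = 0 if mean_kc <= low_edge else (1 if mean_kc <= middle_edge else 2)
                occ[band] += 1
            if nc < N:
                mean_kd = kd / (N - nc)
                sum_K_D += mean_kd
                n_K_D += 1
                band = 0 if mean_kd <= low_edge else (1 if mean_kd <= middle_edge else 2)
                occ[3 + band] += 1
        if thin > 0 and (step + 1) % thin == 0 and row < n_rows:
            seen[:] = 0
            nsub = 0
            for idx in range(N):
                h = phenotype[idx]
                if seen[h] == 0:
                    seen[h] = 1
                    nsub += 1
            traj[row, 0] = step + 1
            traj[row, 1] = nc
            traj[row, 2] = kc / nc if nc > 0 else np.nan
            traj[row, 3] = kd / (N - nc) if nc < N else np.nan
            traj[row, 4] = nsub
            row += 1
    return sum_coop, sum_K_C, n_K_C, sum_K_D, n_K_D, occ, traj


def run(
    params: ModelParams,
    n_steps: int,
    burn_in: int,
    seed: int,
    thin: int = 0,
    traj_path: Optional[str] = None,
    initial: Optional[Population] = None,
    payoff_mode: str = "sampled",
) -> TrajectorySummary:
    """Run the Moran process and report time averages after burn-in.

    Deterministic given ``seed``. The initial population defaults to
    uniformly random strains drawn from the same seed. ``thin > 0``
    additionally records every ``thin``-th step (step, cooperator count,
    mean volume per strategy, number of occupied subpopulations); the table
    is written to ``traj_path`` as TSV when given.
    """
    if not (n_steps > burn_in >= 0):
        raise ValueError(f"need n_steps > burn_in >= 0, got {n_steps}, {burn_in}")
    mode = _mode_code(payoff_mode)
    seed = int(seed) % (2**32)
    if initial is None:
        initial = Population.random(params, np.random.default_rng(seed))
    phenotype = initial.phenotype.astype(np.int64).copy()
    strategy = initial.strategy.astype(np.int64).copy()
    K = initial.K.astype(np.int64).copy()
    sum_coop, sum_K_C, n_K_C, sum_K_D, n_K_D, occ, traj = _run_core(
        phenotype, strategy, K,
        params.N, params.M, params.g, params.r, params.c,
        params.beta, params.theta, params.mu, params.chi_slope,
        int(n_steps), int(burn_in), seed, int(thin),
        5.0, 40.0, mode,
    )
    n_meas = n_steps - burn_in
    occupancy = {}
    for s_idx, strat in enumerate(("C", "D")):
        for b_idx, band in enumerate(_COARSE):
            occupancy[f"{strat}_{band}"] = float(occ[3 * s_idx + b_idx] / n_meas)
    summary = TrajectorySummary(
        mean_cooperator_fraction=sum_coop / n_meas,
        mean_K_by_strategy={
            "C": sum_K_C / n_K_C if n_K_C else float("nan"),
            "D": sum_K_D / n_K_D if n_K_D else float("nan"),
        },
        state_occupancy=occupancy,
        n_steps=n_steps,
        burn_in=burn_in,
        seed=seed,
        params=params,
    )
    if thin > 0 and traj_path is not None:
        import pandas as pd

        pd.DataFrame(
            traj,
            columns=["step", "n_cooperators", "mean_K_C", "mean_K_D", "n_subpopulations"],
        ).astype({"step": int, "n_cooperators": int, "n_subpopulations": int}).to_csv(
            traj_path, sep="\t", index=False, float_format="%.6g"
        )
    return summary


@njit(cache=True)
def _fixation_trials(
    mut_S, mut_K, res_S, res_K, mut_H, res_H,
    N, M, g, r, c, beta, theta, chi_slope, n_reps, seed, mode,
):
    np.random.seed(seed)
    phenotype = np.empty(N, dtype=np.int64)
    strategy = np.empty(N, dtype=np.int64)
    K = np.empty(N, dtype=np.int64)
    payoffs = np.empty(N)
    members = np.empty(N, dtype=np.int64)
    fixed = 0
    for _ in range(n_reps):
        for idx in range(N):
            phenotype[idx] = res_H
            strategy[idx] = res_S
            K[idx] = res_K
        phenotype[0] = mut_H
        strategy[0] = mut_S
        K[0] = mut_K
        while True:
            _one_step(phenotype, strategy, K, payoffs, members, N, M, g, r, c, beta,
                      theta, 0.0, chi_slope, mode)
            n_mut = 0
            for idx in range(N):
                if strategy[idx] == mut_S and K[idx] == mut_K and phenotype[idx] == mut_H:
                    n_mut += 1
            if n_mut == 0:
                break
            if n_mut == N:
                fixed += 1
                break
    return fixed


def simulate_pairwise_fixation(
    mutant: Strain,
    resident: Strain,
    same_phenotype: bool,
    params: ModelParams,
    n_reps: int,
    seed: int,
    payoff_mode: str = "expected",
) -> float:
    """Empirical fixation frequency of a single mutant over ``n_reps`` runs.

    Mutation is switched off, so each replicate ends at one of the two
    absorbing monomorphic states; this is the simulation-side counterpart of
    the analytic fixation probability. The default expected-payoff mode uses
    the exact payoff functions appearing in the analytic Moran transition
    probabilities, so the empirical frequency is an unbiased estimate of the
    analytic value. The two competing types must differ in at least one
    triplet entry; in the different-phenotype setting the mutant needs
    volume >= 2 so a second phenotype exists.
    """
    mutant.validate(params.M)
    resident.validate(params.M)
    if same_phenotype:
        mut_H = res_H = 1
        if mutant == resident:
            raise ValueError("same-phenotype competitors must differ as strains")
    else:
        if mutant.K < 2:
            raise ValueError("different-phenotype competition needs mutant volume >= 2")
        mut_H, res_H = 2, 1
    fixed = _fixation_trials(
        mutant.strategy, mutant.K, resident.strategy, resident.K, mut_H, res_H,
        params.N, params.M, params.g, params.r, params.c,
        params.beta, params.theta, params.chi_slope,
        int(n_reps), int(seed) % (2**32), _mode_code(payoff_mode),
    )
    return fixed / n_reps
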