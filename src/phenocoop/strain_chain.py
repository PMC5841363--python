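"""Embedded Markov chain over the 2M strains in the rare-mutation limit.

When mutations are rare the population is monomorphic almost all of the
time: a mutant lineage either fixes or dies out before the next mutation
arrives. The long-run dynamics then reduce to a jump chain over the ``2M``
monomorphic strain states (cooperative and defective, capacitor volume
``K = 1 .. M``). The rate of moving from resident state ``X`` to state ``Y``
combines the chance that the freshly drawn mutant is a ``Y`` (strategy drawn
uniformly from {C, D}, hence the 1/2; volume uniform on {1..M}, absorbed
into a global scale) with the phenotype-matching probabilities of the
nested-capacitor model and the two fixation probabilities:

    r(X, Y) = H(K_Y - K_X) * [ (1/2) a_Y rho_s + (1/2)(1 - a_Y) rho_d ]
            + (1 - H(K_Y - K_X)) * { (1/2) (K_X - K_Y)/K_X * rho_d
                + (1/2) K_Y/K_X * [ a_Y rho_s + (1 - a_Y) rho_d ] }

with ``a_Y = 1 / K_Y`` (random phenotype switching), ``H(0) = 1``, and
``rho_s`` / ``rho_d`` the fixation probabilities of a single ``Y`` mutant in
an ``X`` population expressing the same / a different phenotype. The
stationary distribution is the normalized left eigenvector of the transition
matrix at eigenvalue 1, and the overall cooperation level is the stationary
mass on cooperative strains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .fixation import FixationQuery, fixation_probability
from .model_core import COOPERATOR, DEFECTOR, ModelParams, Strain

__all__ = [
    "strain_order",
    "strain_position",
    "transition_rate",
    "pairwise_invasion_grid",
    "TransitionMatrix",
    "build_transition_matrix",
    "StationaryResult",
    "stationary_distribution",
    "cooperation_level",
    "coarse_classify",
]


def strain_order(M: int) -> list[Strain]:
    """The 2M strains in chain order.

    Defective strain of volume ``K`` sits at (1-based) odd position
    ``2K - 1``; cooperative strain of volume ``K`` at even position ``2K``.
    """
    order: list[Strain] = []
    for K in range(1, M + 1):
        order.append(Strain(DEFECTOR, K))
        order.append(Strain(COOPERATOR, K))
    return order


def strain_position(strain: Strain) -> int:
    """0-based position of a strain in the chain ordering."""
    return 2 * (strain.K - 1) + (1 if strain.strategy == COOPERATOR else 0)


def transition_rate(X: Strain, Y: Strain, params: ModelParams) -> float:
    """Rate of leaving resident state ``X`` for state ``Y`` via a ``Y`` mutant.

    Omits the mutation rate and the uniform 1/M volume draw, which multiply
    every off-diagonal entry equally and cancel in the stationary
    distribution; the remaining factor 1/2 is the uniform strategy draw.
    """
    X.validate(params.M)
    Y.validate(params.M)
    rho_s = fixation_probability(FixationQuery(Y, X, True, params))
    rho_d = fixation_probability(FixationQuery(Y, X, False, params))
    a_Y = 1.0 / Y.K
    if Y.K >= X.K:  # H(K_Y - K_X) = 1, including ties
        return 0.5 * a_Y * rho_s + 0.5 * (1.0 - a_Y) * rho_d
    cover = Y.K / X.K  # chance the mutant's capacitor covers X's phenotype
    return 0.5 * (1.0 - cover) * rho_d + 0.5 * cover * (a_Y * rho_s + (1.0 - a_Y) * rho_d)


def pairwise_invasion_grid(
    mutant_strategy: int, resident_strategy: int, params: ModelParams
) -> np.ndarray:
    """M x M grid of invasion rates; entry [K_res - 1, K_mut - 1].

    Each entry is the rate the population moves from the resident
    monomorphic state to the mutant's state.
    """
    M = params.M
    grid = np.empty((M, M))
    for K_res in range(1, M + 1):
        X = Strain(resident_strategy, K_res)
        for K_mut in range(1, M + 1):
            grid[K_res - 1, K_mut - 1] = transition_rate(
                X, Strain(mutant_strategy, K_mut), params
            )
    return grid


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic transition matrix of the embedded chain."""

    A: np.ndarray
    params: ModelParams
    scale: float

    def __post_init__(self) -> None:
        n = 2 * self.params.M
        if self.A.shape != (n, n):
            raise ValueError(f"expected shape {(n, n)}, got {self.A.shape}")


def build_transition_matrix(params: ModelParams, scale: float | None = None) -> TransitionMatrix:
    """Assemble the 2M x 2M row-stochastic embedded-chain matrix.

    Off-diagonal entry (i, j) is ``scale * r(strain_i, strain_j)``; the
    diagonal is the row complement. The default ``scale = 1 / M`` is the
    uniform volume-draw factor; any positive scale keeping row sums <= 1
    yields the same stationary distribution (it only rescales the exit rates
    uniformly), which makes the choice safe.
    """
    M = params.M
    if scale is None:
        scale = 1.0 / M
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    order = strain_order(M)
    n = 2 * M
    A = np.zeros((n, n))
    # fixation probabilities vectorised per (resident, mutant) pair
    for i, X in enumerate(order):
        for j, Y in enumerate(order):
            if i == j:
                continue
            A[i, j] = scale * transition_rate(X, Y, params)
    off_sums = A.sum(axis=1)
    if np.any(off_sums > 1.0):
        raise ValueError(
            f"off-diagonal row sum {off_sums.max():.6f} exceeds 1; reduce scale"
        )
    np.fill_diagonal(A, 1.0 - off_sums)
    return TransitionMatrix(A=A, params=params, scale=scale)


@dataclass(frozen=True)
class StationaryResult:
    """Stationary distribution over the 2M strains and derived summaries."""

    pi: np.ndarray
    strains: tuple[Strain, ...]
    cooperation_level: float
    optimal_K_C: int

    def per_strain(self) -> list[tuple[str, int, float]]:
        """(strategy letter, K, probability) rows in chain order."""
        return [
            ("C" if s.strategy == COOPERATOR else "D", s.K, float(p))
            for s, p in zip(self.strains, self.pi)
        ]


def _left_eigvec_unit(A: np.ndarray) -> np.ndarray:
    """Left eigenvector of the eigenvalue closest to 1, renormalised."""
    vals, vecs = scipy.linalg.eig(A.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, idx])
    v = v * np.sign(v.sum())
    if np.any(v < -1e-12):
        raise ValueError(f"stationary eigenvector has negative entry {v.min():.3e}")
    v = np.clip(v, 0.0, None)
    return v / v.sum()


def _null_space_solve(A: np.ndarray) -> np.ndarray:
    """Independent stationary solve: pi (A - I) = 0 with sum(pi) = 1."""
    n = A.shape[0]
    B = (A.T - np.eye(n)).copy()
    B[-1, :] = 1.0
    rhs = np.zeros(n)
    rhs[-1] = 1.0
    v = scipy.linalg.solve(B, rhs)
    if np.any(v < -1e-12):
        raise ValueError(f"null-space stationary solve went negative: {v.min():.3e}")
    v = np.clip(v, 0.0, None)
    return v / v.sum()


def stationary_distribution(tm: TransitionMatrix) -> StationaryResult:
    """Stationary distribution of the embedded chain with cross-checked solve.

    The eigen-decomposition result must agree with an independent linear
    null-space solve to 1e-8 and satisfy ``pi A = pi`` to 1e-10, otherwise
    the chain is numerically degenerate and we fail loudly.
    """
    A = tm.A
    rows = A.sum(axis=1)
    if not np.allclose(rows, 1.0, atol=1e-12):
        raise ValueError("transition matrix is not row-stochastic")
    pi = _left_eigvec_unit(A)
    pi_check = _null_space_solve(A)
    if np.max(np.abs(pi - pi_check)) > 1e-8:
        raise ValueError("stationary solvers disagree beyond 1e-8")
    residual = np.max(np.abs(pi @ A - pi))
    if residual > 1e-10:
        raise ValueError(f"stationary residual {residual:.3e} exceeds 1e-10")
    strains = tuple(strain_order(tm.params.M))
    coop = cooperation_level(pi)
    coop_mass = pi[1::2]
    optimal_K_C = int(np.argmax(coop_mass)) + 1
    return StationaryResult(
        pi=pi, strains=strains, cooperation_level=coop, optimal_K_C=optimal_K_C
    )


def cooperation_level(pi: np.ndarray) -> float:
    """Total stationary mass on cooperative strains (even 1-based positions)."""
    return float(np.sum(pi[1::2]))


def coarse_classify(
    mean_K: float, low: float = 5.0, middle: float = 40.0, high: float = 50.0
) -> str:
    """Classify an average capacitor volume into Low/Middle/High bands.

    Half-open intervals ``(0, low]``, ``(low, middle]``, ``(middle, high]``
    with the conventional boundaries 5 / 40 / 50 for ``M = 50``.
    """
    if not (0.0 < mean_K <= high):
        raise ValueError(f"mean volume {mean_K} outside (0, {high}]")
    if mean_K <= low:
        return "Low"
    if mean_K <= middle:
        return "Middle"
    return "High"
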