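"""Exact Moran-process engine: transition matrix and stationary distribution.

One evolutionary event consists of (i) selecting a "dying" agent — group
``i``, type ``j`` — with probability ``(1/k)(n_ij/n)``, and (ii) drawing its
replacement type: with probability ``mu`` uniformly at random from the type
space, otherwise by global fitness-proportional imitation with weights
``n_st * exp(pi_st)`` summed over groups.  Collecting these one-agent moves
over the enumerated state space yields a row-stochastic transition matrix
``M``; for ``mu > 0`` the chain is irreducible and its unique stationary
distribution (the left eigenvector of ``M`` for eigenvalue 1) describes the
long-run composition of the population.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
import scipy.linalg

from . import states as _states
from .model_core import (
    N_CORE_TYPES,
    StrategyType,
    expected_payoff_table,
    mean_state_payoff,
    validate_state,
)
from .params import ModelParams
from .states import StateIndex, count_states, enumerate_states

__all__ = [
    "death_probability",
    "adoption_probability",
    "build_transition_matrix",
    "stationary_distribution",
    "steady_state_summary",
    "SteadyStateSummary",
    "sweep_exact",
    "default_p_grid",
    "default_bh_grid",
]


def death_probability(state: np.ndarray, group: int, strategy: int) -> float:
    """Probability that an agent in ``group`` of type ``strategy`` dies.

    Equal group sizes are required; the probability is ``(1/k)(n_ij/n)``
    and sums to one over all (group, type) pairs.
    """
    counts = validate_state(state)
    k = counts.shape[0]
    sizes = counts.sum(axis=1)
    if len(set(sizes.tolist())) != 1:
        raise ValueError("exact engine requires equal group sizes")
    n = int(sizes[0])
    return (1.0 / k) * counts[group, strategy] / n


def _adoption_table(params: ModelParams, counts: np.ndarray) -> np.ndarray:
    """Adoption probabilities per target type, vectorized over states.

    ``counts``: (..., k, T) -> (..., T).  Weights are ``n_st e^{pi_st}``
    with payoffs normalized within each state before exponentiation.
    """
    counts = np.asarray(counts, dtype=float)
    pi = expected_payoff_table(params, counts)
    pi = pi - pi.max(axis=(-2, -1), keepdims=True)
    w = counts * np.exp(pi)  # (..., k, T)
    by_type = w.sum(axis=-2)  # (..., T)
    total = by_type.sum(axis=-1, keepdims=True)
    if np.any(total == 0):
        raise ValueError("empty population: no agents to imitate")
    return by_type / total


def adoption_probability(
    params: ModelParams, state: np.ndarray, target_type: int
) -> float:
    """Probability that the adapting agent imitates ``target_type``.

    Imitation is global: the target is drawn fitness-proportionally from
    the whole (pre-death) population, so a type's probability is
    ``sum_s n_sy e^{pi_sy} / sum_t sum_s n_st e^{pi_st}``.
    """
    counts = validate_state(state)
    return float(_adoption_table(params, counts[None, ...])[0, target_type])


@lru_cache(maxsize=8)
def _move_targets(n: int, k: int, T: int) -> tuple[StateIndex, np.ndarray]:
    """State index plus the target-state table for all one-agent moves.

    ``targets[s, i, j, y]`` is the index reached from state ``s`` when an
    agent of type ``j`` in group ``i`` switches to type ``y``; moves with
    ``n_ij = 0`` keep ``s`` (they carry zero probability).
    """
    space = enumerate_states(n, k, T)
    S = len(space)
    targets = np.empty((S, k, T, T), dtype=np.int64)
    for i in range(k):
        for j in range(T):
            for y in range(T):
                if y == j:
                    targets[:, i, j, y] = np.arange(S)
                    continue
                for s in range(S):
                    if space.counts[s, i, j] == 0:
                        targets[s, i, j, y] = s
                    else:
                        c = space.counts[s].copy()
                        c[i, j] -= 1
                        c[i, y] += 1
                        targets[s, i, j, y] = space.index(c)
    return space, targets


def build_transition_matrix(
    params: ModelParams,
    T: int = N_CORE_TYPES,
    mutation_includes_current: bool = True,
    state_cap: int = _states.DEFAULT_STATE_CAP,
) -> tuple[np.ndarray, StateIndex]:
    """Dense row-stochastic one-event transition matrix over all states.

    ``mutation_includes_current`` controls the mutation target
    distribution: uniform over all ``T`` types (default; the effective
    mutation rate is then ``mu (T-1)/T``) or uniform over the ``T-1``
    other types.
    """
    n, k, mu = params.n, params.k, params.mu
    total = count_states(n, k, T)
    if total > state_cap:
        raise ValueError(
            f"state space has {total:,} states, above cap {state_cap:,}"
        )
    space, targets = _move_targets(n, k, T)
    S = len(space)
    counts = space.counts.astype(float)

    adopt = _adoption_table(params, counts)  # (S, T)
    death = counts / (k * n)  # (S, k, T)

    M = np.zeros((S, S))
    rows = np.arange(S)
    diag = np.zeros(S)
    for i in range(k):
        for j in range(T):
            for y in range(T):
                if mutation_includes_current:
                    mut = 1.0 / T
                else:
                    mut = 0.0 if y == j else 1.0 / (T - 1)
                prob = death[:, i, j] * (mu * mut + (1 - mu) * adopt[:, y])
                if y == j:
                    diag += prob
                else:
                    np.add.at(M, (rows, targets[:, i, j, y]), prob)
    M[rows, rows] += diag
    return M, space


def _check_row_stochastic(M: np.ndarray) -> None:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(M < -1e-15):
        raise ValueError("transition matrix has negative entries")
    if np.max(np.abs(M.sum(axis=1) - 1.0)) > 1e-10:
        raise ValueError("transition matrix rows must sum to 1")


def stationary_distribution(
    M: np.ndarray, backend: str = "solve", tol: float = 1e-12
) -> np.ndarray:
    """Stationary distribution ``w`` with ``w M = w``, ``sum(w) = 1``.

    Three interchangeable backends are provided and must agree:

    * ``"solve"`` — linear solve of the null-space system ``(M^T - I) w = 0``
      with the normalization row appended (default; fast and exact to
      machine precision for irreducible chains);
    * ``"eig"`` — dense left eigendecomposition, eigenvalue closest to 1;
    * ``"power"`` — repeated squaring of ``M`` until its rows coincide.

    Raises ``ValueError`` for a reducible chain (e.g. ``mu = 0``), whose
    long-run behavior depends on the initial state; analyse absorption
    instead.
    """
    M = np.asarray(M, dtype=float)
    _check_row_stochastic(M)
    S = M.shape[0]
    if backend == "solve":
        A = M.T - np.eye(S)
        A[-1, :] = 1.0
        b = np.zeros(S)
        b[-1] = 1.0
        try:
            w = scipy.linalg.solve(A, b)
        except scipy.linalg.LinAlgError as err:
            raise ValueError(
                "singular stationary system: the chain appears reducible "
                "(mu = 0?); use absorption analysis instead"
            ) from err
    elif backend == "eig":
        vals, vecs = scipy.linalg.eig(M.T)
        order = np.argsort(np.abs(vals - 1.0))
        near_one = np.sum(np.abs(vals - 1.0) < 1e-10)
        if near_one > 1:
            raise ValueError(
                "multiple unit eigenvalues: the chain is reducible (mu = 0?); "
                "use absorption analysis instead"
            )
        w = np.real(vecs[:, order[0]])
        w = w / w.sum()
    elif backend == "power":
        P = M.copy()
        for _ in range(200):
            P = P @ P
            if np.max(P.max(axis=0) - P.min(axis=0)) < tol:
                break
        else:
            raise ValueError(
                "power iteration did not converge: the chain mixes too "
                "slowly or is reducible (mu = 0?)"
            )
        w = P.mean(axis=0)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    if np.any(w < -1e-8):
        raise ValueError("stationary solve produced negative mass; chain reducible?")
    w = np.clip(w, 0.0, None)
    w = w / w.sum()
    resid = np.max(np.abs(w @ M - w))
    if resid > 1e-8:
        raise ValueError(f"stationary residual {resid:.2e} exceeds 1e-8")
    return w


@dataclass(frozen=True)
class SteadyStateSummary:
    """Stationary-expectation summaries of the population composition."""

    prop_U: float
    prop_P: float
    prop_F: float
    welfare: float
    state_count: int

    @property
    def proportions(self) -> np.ndarray:
        return np.array([self.prop_U, self.prop_P, self.prop_F])


def steady_state_summary(
    params: ModelParams,
    backend: str = "solve",
    mutation_includes_current: bool = True,
) -> SteadyStateSummary:
    """Long-run type proportions and welfare under the stationary law.

    Proportions are stationary expectations of type counts over ``N``;
    welfare is the stationary expectation of the population-mean expected
    payoff per generation (both stage endowments included).
    """
    if params.mu <= 0:
        raise ValueError(
            "mu = 0 makes homogeneous states absorbing and the stationary "
            "distribution non-unique; use absorption analysis (ABM) instead"
        )
    M, space = build_transition_matrix(
        params, mutation_includes_current=mutation_includes_current
    )
    w = stationary_distribution(M, backend=backend)
    shares = space.counts.sum(axis=1) / params.N  # (S, T)
    props = w @ shares
    welfare = float(w @ mean_state_payoff(params, space.counts))
    return SteadyStateSummary(
        prop_U=float(props[StrategyType.UNIVERSALIST]),
        prop_P=float(props[StrategyType.PAROCHIALIST]),
        prop_F=float(props[StrategyType.FREE_RIDER]),
        welfare=welfare,
        state_count=len(space),
    )


def default_p_grid() -> np.ndarray:
    """In-group meeting probabilities 0.5, 0.51, ..., 1.0 (51 values)."""
    return np.round(np.arange(0.50, 1.0 + 1e-9, 0.01), 10)


def default_bh_grid() -> np.ndarray:
    """Helping benefits 0, 0.1, ..., 9 (91 values)."""
    return np.round(np.arange(0.0, 9.0 + 1e-9, 0.1), 10)


def sweep_exact(
    base_params: ModelParams,
    p_grid: np.ndarray | None = None,
    bh_grid: np.ndarray | None = None,
    backend: str = "solve",
) -> pd.DataFrame:
    """Steady-state summary for every ``(p, b_h)`` grid cell.

    The default grids (51 x 91 = 4641 cells) cover the canonical sweep of
    boundary fluidity against helping benefit at the baseline two-group
    parameters.  Returns one row per cell with columns
    ``(p, b_h, prop_U, prop_P, prop_F, welfare, n, k, mu, state_count)``.
    """
    p_grid = default_p_grid() if p_grid is None else np.asarray(p_grid, dtype=float)
    bh_grid = default_bh_grid() if bh_grid is None else np.asarray(bh_grid, dtype=float)
    rows = []
    for p in p_grid:
        for bh in bh_grid:
            params = base_params.replace(p=float(p), b_h=float(bh))
            s = steady_state_summary(params, backend=backend)
            rows.append(
                {
                    "p": float(p),
                    "b_h": float(bh),
                    "prop_U": s.prop_U,
                    "prop_P": s.prop_P,
                    "prop_F": s.prop_F,
                    "welfare": s.welfare,
                    "n": params.n,
                    "k": params.k,
                    "mu": params.mu,
                    "state_count": s.state_count,
                }
            )
    return pd.DataFrame(rows)
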