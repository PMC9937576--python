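"""Agent-based simulator for large and fragmented populations.

The simulator replicates the exact engine's rules with *realized* (rather
than expected) interactions: every iteration each agent earns its stage-1
return from the actually chosen contributions, is paired with a concrete
receiver (in-group with probability ``p``), pays/receives realized help,
and then a single Moran event updates one agent's strategy by mutation or
global fitness-proportional imitation with weights ``e^payoff``.

Two engines produce the same stochastic model: a plain-NumPy path that
supports the full extended strategy space (history-conditioned helping,
second-order free-riders, ...), and a compiled fast path
(:mod:`coopevo._kernels`) restricted to the canonical (U, P, F) space,
used for long time averages and parameter sweeps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._kernels import core3_kernel
from .params import ModelParams
from .strategies import StrategySpace, core_space

__all__ = [
    "AgentPopulation",
    "RunResult",
    "init_population",
    "pair_agents",
    "iterate",
    "run_simulation",
    "time_average_shares",
    "sweep_abm",
    "summarize_sweep",
    "canonical_design",
    "design_slots",
]

#: Iteration cap and tail-averaging window of the canonical design.
DEFAULT_MAX_ITER = 2000
DEFAULT_TAIL_WINDOW = 1000


@dataclass
class AgentPopulation:
    """Per-agent roster: group ids (contiguous equal blocks) and strategies.

    Group membership is fixed; only strategies change over time.
    ``helped_prev`` carries each agent's previous-round helping flag for
    history-conditioned rules (initialized to the benefit-of-the-doubt
    value).
    """

    groups: np.ndarray  # int64[N]
    strategies: np.ndarray  # int64[N], indices into `space`
    space: StrategySpace
    helped_prev: np.ndarray = field(default=None)  # bool[N]

    def __post_init__(self) -> None:
        if self.helped_prev is None:
            self.helped_prev = np.ones(len(self.groups), dtype=bool)
        if len(self.groups) != len(self.strategies):
            raise ValueError("groups and strategies must have equal length")

    @property
    def N(self) -> int:
        return len(self.groups)

    @property
    def k(self) -> int:
        return int(self.groups.max()) + 1

    @property
    def n(self) -> int:
        return self.N // self.k

    def counts(self) -> np.ndarray:
        """Derived ``k x T`` count matrix (a valid population state)."""
        T = len(self.space)
        out = np.zeros((self.k, T), dtype=np.int64)
        np.add.at(out, (self.groups, self.strategies), 1)
        return out

    def shares(self) -> np.ndarray:
        return self.counts().sum(axis=0) / self.N

    def is_homogeneous(self) -> bool:
        return bool(np.all(self.strategies == self.strategies[0]))


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def init_population(
    params: ModelParams, seed_or_rng=None, space: StrategySpace | None = None
) -> AgentPopulation:
    """Random initial population: strategies i.i.d. uniform over the space."""
    space = core_space() if space is None else space
    rng = _as_rng(seed_or_rng)
    if params.N % params.k != 0:
        raise ValueError("N must be divisible by k")
    groups = np.repeat(np.arange(params.k), params.n)
    strategies = rng.integers(len(space), size=params.N)
    return AgentPopulation(groups=groups, strategies=strategies, space=space)


def pair_agents(pop: AgentPopulation, p: float, seed_or_rng=None) -> np.ndarray:
    """Assign each donor a receiver: in-group w.p. ``p``, else out-group.

    Receivers are drawn uniformly within the chosen pool and never equal
    the donor; receivers may be chosen by several donors independently.
    """
    rng = _as_rng(seed_or_rng)
    N, n, k = pop.N, pop.n, pop.k
    if p > 0 and n < 2:
        raise ValueError("in-group pairing (p > 0) requires group size >= 2")
    if p < 1 and k < 2:
        raise ValueError("out-group pairing (p < 1) requires at least 2 groups")
    agents = np.arange(N)
    in_group = rng.random(N) < p
    recv = np.empty(N, dtype=np.int64)
    # in-group: uniform among the n-1 other members of the own block
    j = rng.integers(0, max(n - 1, 1), size=N)
    off = agents - pop.groups * n
    j = np.where(j >= off, j + 1, j)
    recv_in = pop.groups * n + j
    # out-group: uniform among the N-n members outside the own block
    m = rng.integers(0, max(N - n, 1), size=N)
    recv_out = np.where(m >= pop.groups * n, m + n, m)
    recv[in_group] = recv_in[in_group]
    recv[~in_group] = recv_out[~in_group]
    return recv


def _realized_payoffs(
    pop: AgentPopulation,
    params: ModelParams,
    receivers: np.ndarray,
    detection: str = "history",
) -> tuple[np.ndarray, np.ndarray]:
    """Stage-1 + stage-2 realized payoffs and the per-agent helping flags.

    ``detection`` governs what history-conditioned helpers see about a
    receiver's second-order reputation: ``"history"`` uses the receiver's
    factual previous-round helping flag (noisy — a helper whose rule did
    not fire last round looks like a nonhelper), ``"disposition"`` models
    perfect detection of nonhelping types (the receiver's strategy never
    helps).
    """
    space = pop.space
    strat = pop.strategies
    contrib = space.contrib_code[strat]  # 0 none, 1 club, 2 public
    N, n = pop.N, pop.n

    pub_total = int((contrib == 2).sum())
    club_by_group = np.bincount(pop.groups[contrib == 1], minlength=pop.k)
    pay = np.where(contrib == 0, params.e, params.e - params.c_c).astype(float)
    pay += pub_total * params.b_PG / N
    pay += club_by_group[pop.groups] * params.b_CG / n
    pay += params.e  # stage-2 endowment

    rule = space.rule_code[strat]
    cond = space.conditional[strat]
    recv_action = contrib[receivers]
    same_group = pop.groups == pop.groups[receivers]
    base = np.select(
        [rule == 0, rule == 1, rule == 2, rule == 3],
        [
            np.zeros(N, dtype=bool),
            recv_action == 2,
            (recv_action == 1) & same_group,
            recv_action >= 1,
        ],
    ).astype(bool)
    if detection == "history":
        reputation = pop.helped_prev[receivers]
    elif detection == "disposition":
        reputation = space.is_helper[strat[receivers]]
    else:
        raise ValueError(f"unknown detection mode {detection!r}")
    helps = base & (~cond | reputation)
    pay[helps] -= params.c_h
    np.add.at(pay, receivers[helps], params.b_h)
    return pay, helps


def iterate(
    pop: AgentPopulation,
    params: ModelParams,
    rng: np.random.Generator,
    payoff_blind: bool = False,
    expected_fitness: bool = False,
    mutation_includes_current: bool = True,
    detection: str = "history",
) -> np.ndarray:
    """Advance the population by one iteration in place; returns payoffs.

    One iteration = realized stage-1 earnings, realized stage-2 pairing
    and helping, then a single Moran event (uniform dying agent; mutation
    with probability ``mu``, else imitation proportional to ``e^payoff``).
    ``expected_fitness`` swaps the imitation weights for the closed-form
    expected payoffs (canonical three-type space only).
    """
    receivers = pair_agents(pop, params.p, rng)
    pay, helps = _realized_payoffs(pop, params, receivers, detection=detection)
    pop.helped_prev = helps

    die = int(rng.integers(pop.N))
    T = len(pop.space)
    if rng.random() < params.mu:
        if mutation_includes_current:
            new = int(rng.integers(T))
        else:
            new = int(rng.integers(T - 1))
            if new >= pop.strategies[die]:
                new += 1
    else:
        if payoff_blind:
            weights = np.ones(pop.N)
        elif expected_fitness:
            if not pop.space.is_core3:
                raise ValueError(
                    "expected-payoff fitness is defined for the canonical "
                    "three-type space only"
                )
            from .model_core import expected_payoff_table

            table = expected_payoff_table(params, pop.counts()[None, ...])[0]
            pi = table[pop.groups, pop.strategies]
            weights = np.exp(pi - pi.max())
        else:
            weights = np.exp(pay - pay.max())
        c = np.cumsum(weights)
        m = int(np.searchsorted(c, rng.random() * c[-1], side="right"))
        new = int(pop.strategies[min(m, pop.N - 1)])
    pop.strategies[die] = new
    return pay


@dataclass(frozen=True)
class RunResult:
    """Outcome of a single simulation run."""

    converged: bool
    iterations: int  # iterations executed before homogeneity, or the cap
    final_composition: np.ndarray  # type shares, sums to 1
    seed: int
    trajectory: np.ndarray | None = None  # (iterations, T) type counts


def _seed_to_uint(seed_or_rng) -> int:
    if isinstance(seed_or_rng, np.random.Generator):
        return int(seed_or_rng.integers(2**31))
    if seed_or_rng is None:
        return int(np.random.SeedSequence().generate_state(1)[0] % 2**31)
    return int(np.random.SeedSequence(seed_or_rng).generate_state(1)[0] % 2**31)


def run_simulation(
    params: ModelParams,
    seed=None,
    space: StrategySpace | None = None,
    max_iter: int = DEFAULT_MAX_ITER,
    tail_window: int = DEFAULT_TAIL_WINDOW,
    engine: str = "auto",
    record_trajectory: bool = False,
    payoff_blind: bool = False,
    expected_fitness: bool = False,
    detection: str = "history",
) -> RunResult:
    """Run one simulation from a random initial composition.

    The run stops as soon as the population is homogeneous; otherwise it
    is capped at ``max_iter`` iterations and the reported composition is
    the mean of the type shares over the last ``tail_window`` iterations.

    ``engine="fast"`` (compiled, canonical three-type space only) and
    ``engine="python"`` (any strategy space) realize the same model;
    ``"auto"`` picks the fast path whenever it applies.
    """
    space = core_space() if space is None else space
    if engine == "auto":
        engine = "fast" if (space.is_core3 and not record_trajectory) else "python"
    seed_u = _seed_to_uint(seed)

    if engine == "fast":
        if not space.is_core3:
            raise ValueError("fast engine supports the canonical three-type space only")
        rng = np.random.default_rng(seed_u)
        strat = rng.integers(3, size=params.N).astype(np.int64)
        conv_iter, comp, _ = core3_kernel(
            strat,
            params.k,
            params.n,
            params.e,
            params.c_c,
            params.c_h,
            params.b_CG,
            params.b_PG,
            params.b_h,
            params.p,
            params.mu,
            seed_u,
            max_iter,
            True,
            tail_window,
            0,
            0,
            payoff_blind,
            expected_fitness,
            True,
        )
        converged = conv_iter >= 0
        return RunResult(
            converged=converged,
            iterations=int(conv_iter) if converged else max_iter,
            final_composition=np.asarray(comp),
            seed=seed_u,
        )

    rng = np.random.default_rng(seed_u)
    pop = init_population(params, rng, space=space)
    T = len(space)
    history: list[np.ndarray] = []
    for it in range(max_iter):
        if pop.is_homogeneous():
            traj = np.array(history, dtype=np.int64) if record_trajectory else None
            return RunResult(
                converged=True,
                iterations=it,
                final_composition=pop.shares(),
                seed=seed_u,
                trajectory=traj,
            )
        iterate(
            pop,
            params,
            rng,
            payoff_blind=payoff_blind,
            expected_fitness=expected_fitness,
            detection=detection,
        )
        history.append(pop.counts().sum(axis=0))
    tail = np.array(history[-tail_window:], dtype=float)
    comp = tail.mean(axis=0) / params.N
    traj = np.array(history, dtype=np.int64) if record_trajectory else None
    return RunResult(
        converged=False,
        iterations=max_iter,
        final_composition=comp,
        seed=seed_u,
        trajectory=traj,
    )


def time_average_shares(
    params: ModelParams,
    n_iter: int,
    seed=None,
    burn_in: float | int = 0.5,
    n_batches: int = 20,
    expected_fitness: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Long-run time-averaged type shares with Monte-Carlo standard errors.

    Runs the compiled three-type simulator for ``n_iter`` iterations with
    mutation switched on, discards ``burn_in`` (a fraction if < 1, else an
    iteration count), and estimates the stationary type shares by the mean
    over the remainder.  Standard errors come from ``n_batches`` batch
    means, which absorbs the heavy autocorrelation of the slowly mixing
    chain at small ``mu``.
    """
    if params.mu <= 0:
        raise ValueError("time averages require mu > 0 (ergodic chain)")
    burn = int(burn_in * n_iter) if burn_in < 1 else int(burn_in)
    seed_u = _seed_to_uint(seed)
    rng = np.random.default_rng(seed_u)
    strat = rng.integers(3, size=params.N).astype(np.int64)
    _, _, batch_means = core3_kernel(
        strat,
        params.k,
        params.n,
        params.e,
        params.c_c,
        params.c_h,
        params.b_CG,
        params.b_PG,
        params.b_h,
        params.p,
        params.mu,
        seed_u,
        n_iter,
        False,
        1,
        burn,
        n_batches,
        False,
        expected_fitness,
        True,
    )
    batch_means = np.asarray(batch_means)
    mean = batch_means.mean(axis=0)
    se = batch_means.std(axis=0, ddof=1) / math.sqrt(n_batches)
    return mean, se


def second_order_experiment(
    params: ModelParams | None = None,
    n_pairs: int = 50,
    base_seed: int = 0,
    n_iter: int = 12000,
) -> pd.DataFrame:
    """Paired comparison: does undetectable second-order free-riding collapse cooperation?

    Two conditions share seeds.  Both extend the space with second-order
    free-riders of either contribution kind (cooperate in stage 1, never
    help).  In the *undetectable* condition helpers cannot distinguish
    them from fellow helpers; in the *detectable* control, helpers detect
    nonhelping types and withhold help from them.  Each run reports the
    time-averaged pure free-rider share over the second half of ``n_iter``
    iterations (mutation stays on; runs do not stop at homogeneity).

    Defaults use a cooperative regime (``b_h = 7``, ``p = 0.5``) with two
    groups of eight (a five-strategy space needs more than eight agents
    for selection to beat initialization noise) and an elevated mutation
    rate ``mu = 1e-3`` so that invasion sequences — second-order
    free-riders displacing helpers, then defectors invading — play out
    within a desk-scale horizon.
    """
    from .strategies import (
        DETECTING_PAROCHIALIST,
        DETECTING_UNIVERSALIST,
        FREE_RIDER,
        PAROCHIALIST,
        SECOND_ORDER_FREE_RIDER,
        SECOND_ORDER_FREE_RIDER_CLUB,
        UNIVERSALIST,
    )

    if params is None:
        params = ModelParams(n=8, b_h=7.0, p=0.5, mu=1e-3)
    undet = StrategySpace(
        (UNIVERSALIST, PAROCHIALIST, FREE_RIDER,
         SECOND_ORDER_FREE_RIDER, SECOND_ORDER_FREE_RIDER_CLUB)
    )
    det = StrategySpace(
        (DETECTING_UNIVERSALIST, DETECTING_PAROCHIALIST, FREE_RIDER,
         SECOND_ORDER_FREE_RIDER, SECOND_ORDER_FREE_RIDER_CLUB)
    )
    f_index = 2  # pure free-rider position in both spaces

    def mean_free_rider_share(space: StrategySpace, seed: int, detection: str) -> float:
        rng = np.random.default_rng(seed)
        pop = init_population(params, rng, space=space)
        acc, cnt = 0.0, 0
        for it in range(n_iter):
            iterate(pop, params, rng, detection=detection)
            if it >= n_iter // 2:
                acc += pop.shares()[f_index]
                cnt += 1
        return acc / cnt

    rows = []
    for i in range(n_pairs):
        seed = int(
            np.random.SeedSequence(base_seed, spawn_key=(i,)).generate_state(1)[0] % 2**31
        )
        rows.append(
            {
                "pair": i,
                "seed": seed,
                "free_rider_share_undetectable": mean_free_rider_share(undet, seed, "history"),
                "free_rider_share_detectable": mean_free_rider_share(det, seed, "disposition"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sweep design


def canonical_design(
    p_grid: Sequence[float] | None = None,
    bh_grid: Sequence[float] | None = None,
    group_size_n: Sequence[int] = (4, 8, 16, 32, 64),
    fragmentation_k: Sequence[int] = (2, 4, 8, 16, 32),
    fragmentation_N: int = 128,
    group_size_k: int = 8,
) -> list[dict]:
    """The canonical two-manipulation sweep design as a list of cells.

    Manipulation "group_size" fixes ``k`` groups and varies the group size
    ``n``; manipulation "fragmentation" fixes the population size ``N``
    and varies the number of groups ``k``.  Both cross the fluidity grid
    ``p = 0.5, 0.55, ..., 1.0`` with the helping-benefit grid
    ``b_h = 1, 1.2, ..., 4`` by default.
    """
    if p_grid is None:
        p_grid = np.round(np.arange(0.5, 1.0 + 1e-9, 0.05), 10)
    if bh_grid is None:
        bh_grid = np.round(np.arange(1.0, 4.0 + 1e-9, 0.2), 10)
    cells: list[dict] = []
    for n in group_size_n:
        for p in p_grid:
            for bh in bh_grid:
                cells.append(
                    dict(manipulation="group_size", k=group_size_k, n=int(n),
                         p=float(p), b_h=float(bh))
                )
    for k in fragmentation_k:
        if fragmentation_N % k:
            raise ValueError(f"N={fragmentation_N} not divisible by k={k}")
        for p in p_grid:
            for bh in bh_grid:
                cells.append(
                    dict(manipulation="fragmentation", k=int(k),
                         n=fragmentation_N // int(k), p=float(p), b_h=float(bh))
                )
    return cells


def design_slots(design: Iterable[dict], runs_per_cell: int) -> int:
    """Total number of independent simulation runs a design requires."""
    return sum(1 for _ in design) * runs_per_cell


def sweep_abm(
    design: Sequence[dict],
    runs_per_cell: int,
    base_params: ModelParams | None = None,
    base_seed: int = 0,
    space: StrategySpace | None = None,
    max_iter: int = DEFAULT_MAX_ITER,
    engine: str = "auto",
) -> pd.DataFrame:
    """Execute a sweep design; one row per run.

    Each cell overrides ``(k, n, p, b_h)`` (and optionally other
    :class:`ModelParams` fields) on ``base_params``.  Run seeds are derived
    deterministically from ``(base_seed, cell index, run index)`` so cells
    can be re-run independently.
    """
    base_params = ModelParams() if base_params is None else base_params
    space = core_space() if space is None else space
    names = space.names
    rows = []
    for ci, cell in enumerate(design):
        overrides = {k: v for k, v in cell.items() if k != "manipulation"}
        params = base_params.replace(**overrides)
        for ri in range(runs_per_cell):
            seed = int(
                np.random.SeedSequence(base_seed, spawn_key=(ci, ri)).generate_state(1)[0]
                % 2**31
            )
            res = run_simulation(
                params, seed=seed, space=space, max_iter=max_iter, engine=engine
            )
            row = {
                "manipulation": cell.get("manipulation", ""),
                "k": params.k,
                "n": params.n,
                "N": params.N,
                "p": params.p,
                "b_h": params.b_h,
                "mu": params.mu,
                "run": ri,
                "seed": res.seed,
                "converged": res.converged,
                "iterations": res.iterations,
            }
            for t, name in enumerate(names):
                row[f"share_{name}"] = float(res.final_composition[t])
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_sweep(runs: pd.DataFrame) -> pd.DataFrame:
    """Per-cell summaries: mean type shares, convergence rate, mean iterations."""
    share_cols = [c for c in runs.columns if c.startswith("share_")]
    keys = ["manipulation", "k", "n", "N", "p", "b_h"]
    agg = {c: "mean" for c in share_cols}
    agg["converged"] = "mean"
    agg["iterations"] = "mean"
    out = runs.groupby(keys, as_index=False).agg(agg)
    return out.rename(columns={"converged": "convergence_rate", "iterations": "mean_iterations"})
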