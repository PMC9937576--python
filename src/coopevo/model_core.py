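"""Game structure: strategy types, stage-1 earnings, expected payoffs, fitness.

The core strategy space has exactly three types:

* ``UNIVERSALIST`` (U) — invests in the public good and helps other
  universal cooperators wherever it meets them;
* ``PAROCHIALIST`` (P) — invests in the own group's club good and helps
  fellow parochialists of the own group;
* ``FREE_RIDER`` (F) — neither contributes nor helps.

A population state is a ``k x T`` matrix of nonnegative counts, row ``i``
holding the composition of group ``i`` and summing to the group size.
"""

from __future__ import annotations

import enum
from typing import Sequence

import numpy as np

from .params import ModelParams

__all__ = [
    "StrategyType",
    "Action",
    "N_CORE_TYPES",
    "stage1_earnings",
    "expected_payoff",
    "expected_payoff_table",
    "mean_state_payoff",
    "selection_weights",
    "validate_state",
]


class StrategyType(enum.IntEnum):
    """The three core strategy types (indices into state columns)."""

    UNIVERSALIST = 0
    PAROCHIALIST = 1
    FREE_RIDER = 2


class Action(str, enum.Enum):
    """Stage-1 contribution actions."""

    PUBLIC = "public"
    CLUB = "club"
    NONE = "none"


N_CORE_TYPES = 3

#: Stage-1 action implied by each core type.
CORE_ACTIONS = {
    StrategyType.UNIVERSALIST: Action.PUBLIC,
    StrategyType.PAROCHIALIST: Action.CLUB,
    StrategyType.FREE_RIDER: Action.NONE,
}


def validate_state(counts: np.ndarray, n: int | None = None) -> np.ndarray:
    """Validate a ``k x T`` count matrix; returns it as an int array.

    Every entry must be a nonnegative integer; if ``n`` is given, every
    group row must sum to ``n`` (equal group sizes).
    """
    counts = np.asarray(counts)
    if counts.ndim != 2:
        raise ValueError(f"state must be a k x T matrix, got shape {counts.shape}")
    if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
        if not np.all(counts == np.floor(counts)) or np.any(counts < 0):
            raise ValueError("state counts must be nonnegative integers")
    counts = counts.astype(np.int64)
    if n is not None and np.any(counts.sum(axis=1) != n):
        raise ValueError(f"every group row must sum to the group size {n}")
    return counts


def stage1_earnings(
    params: ModelParams,
    contributions: Sequence[str | Action],
    groups: Sequence[int] | None = None,
) -> np.ndarray:
    """Per-agent stage-1 earnings for a realized profile of contributions.

    Each agent keeps the endowment ``e`` if it plays ``none`` and otherwise
    pays the cooperation cost ``c_c``; every public contribution is
    multiplied by ``b_PG`` and shared over all ``N`` agents, every club
    contribution by ``b_CG`` and shared over the contributor's group.

    Parameters
    ----------
    contributions : one action per agent (``"public"``, ``"club"``, ``"none"``)
    groups : group id per agent; defaults to ``k`` contiguous blocks of ``n``.

    Returns
    -------
    earnings : float array of length ``N`` (monetary units)
    """
    N = params.N
    if len(contributions) != N:
        raise ValueError(f"expected {N} actions (one per agent), got {len(contributions)}")
    actions = [Action(a) for a in contributions]
    if groups is None:
        groups = np.repeat(np.arange(params.k), params.n)
    else:
        groups = np.asarray(groups, dtype=np.int64)
        if groups.shape != (N,):
            raise ValueError("groups must assign one group id per agent")
    group_ids, group_sizes = np.unique(groups, return_counts=True)
    size_of = dict(zip(group_ids.tolist(), group_sizes.tolist()))

    is_public = np.array([a is Action.PUBLIC for a in actions])
    is_club = np.array([a is Action.CLUB for a in actions])
    pub_total = int(is_public.sum())
    club_total = {g: int(is_club[groups == g].sum()) for g in group_ids}

    earnings = np.full(N, params.e, dtype=float)
    earnings[is_public | is_club] -= params.c_c
    earnings += pub_total * params.b_PG / N
    for g in group_ids:
        earnings[groups == g] += club_total[g] * params.b_CG / size_of[g]
    return earnings


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Elementwise num/den with the convention 0 where den == 0.

    A vanishing denominator means no partner of that kind exists, so the
    corresponding meeting probability is zero.
    """
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.zeros(np.broadcast_shapes(num.shape, den.shape))
    np.divide(num, den, out=out, where=den != 0)
    return out


def expected_payoff_table(params: ModelParams, counts: np.ndarray) -> np.ndarray:
    """Expected total payoff of every (group, type), vectorized over states.

    ``counts`` has shape ``(..., k, T)`` with ``T = 3`` core types; the
    result has the same shape.  Entry ``[..., i, t]`` is the expected
    two-stage payoff of an agent of type ``t`` residing in group ``i``:

        pi_F = 2e + n_U b_PG / N + n_P^i b_CG / n_i
        pi_P = pi_F - c_c + p (n_P^i - 1)/(n_i - 1) (b_h - c_h)
        pi_U = pi_F - c_c + [p (n_U^i - 1)/(n_i - 1)
                             + (1-p) (n_U - n_U^i)/(N - n_i)] (b_h - c_h)

    The helping terms are the probabilities of being matched with another
    agent of the focal helping class, in-group with probability ``p`` and
    out-group (uniform over all out-group members) with probability
    ``1 - p``.  Payoffs of types with zero count are evaluated with the
    counts as given; they enter the dynamics weighted by the count and so
    never contribute.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape[-1] != N_CORE_TYPES:
        raise ValueError("expected T = 3 core types in the last axis")
    U, P, F = StrategyType.UNIVERSALIST, StrategyType.PAROCHIALIST, StrategyType.FREE_RIDER
    n_i = counts.sum(axis=-1)  # (..., k)
    N = n_i.sum(axis=-1, keepdims=True)  # (..., 1)
    nU_i = counts[..., U]
    nP_i = counts[..., P]
    nU = nU_i.sum(axis=-1, keepdims=True)  # (..., 1)

    net_help = params.b_h - params.c_h
    common = (
        2.0 * params.e
        + nU * params.b_PG / np.maximum(N, 1)
        + _safe_div(nP_i * params.b_CG, n_i)
    )
    meet_U = params.p * _safe_div(nU_i - 1, n_i - 1) + (1.0 - params.p) * _safe_div(
        nU - nU_i, N - n_i
    )
    meet_P = params.p * _safe_div(nP_i - 1, n_i - 1)

    out = np.empty_like(counts)
    out[..., F] = common
    out[..., P] = common - params.c_c + meet_P * net_help
    out[..., U] = common - params.c_c + meet_U * net_help
    return out


def expected_payoff(
    params: ModelParams,
    state: np.ndarray,
    group: int,
    strategy: StrategyType,
    as_resident: bool = False,
) -> float:
    """Expected payoff of an agent of ``strategy`` in ``group`` at ``state``.

    With ``as_resident=True`` and the focal type absent from the focal
    group, the payoff is that of a hypothetical resident: the focal count
    is raised to 1 in the focal agent's own meeting terms (useful for
    invasion analyses).  The default evaluates the printed equations with
    the counts exactly as given.
    """
    counts = validate_state(state)
    if not (0 <= group < counts.shape[0]):
        raise IndexError(f"group {group} out of range for k={counts.shape[0]}")
    if as_resident and counts[group, strategy] == 0:
        counts = counts.copy()
        counts[group, strategy] = 1
        # keep group sizes intact: the hypothetical resident displaces a
        # free-rider if possible, else the most common other type
        others = [t for t in StrategyType if t != strategy]
        others.sort(key=lambda t: -counts[group, t])
        for t in ([StrategyType.FREE_RIDER] + others):
            if t != strategy and counts[group, t] > 0:
                counts[group, t] -= 1
                break
    table = expected_payoff_table(params, counts[None, ...])
    return float(table[0, group, strategy])


def mean_state_payoff(params: ModelParams, counts: np.ndarray) -> np.ndarray:
    """Population-mean expected payoff per agent, vectorized over states.

    ``counts`` has shape ``(..., k, T)``; the result drops the last two
    axes.  This is the per-generation welfare measure (it includes both
    stage endowments).
    """
    counts = np.asarray(counts, dtype=float)
    table = expected_payoff_table(params, counts)
    N = counts.sum(axis=(-2, -1))
    return (counts * table).sum(axis=(-2, -1)) / N


def selection_weights(payoffs: np.ndarray) -> np.ndarray:
    """Exponential fitness ``e^pi``, normalized within the state for stability.

    The maximum payoff is subtracted before exponentiation, which preserves
    all fitness ratios while avoiding overflow; the returned weights are
    therefore ``e^(pi - max pi)``.
    """
    payoffs = np.asarray(payoffs, dtype=float)
    if not np.all(np.isfinite(payoffs)):
        raise ValueError("payoffs must be finite")
    return np.exp(payoffs - payoffs.max())
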