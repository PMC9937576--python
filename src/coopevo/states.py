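"""Enumeration of the Markov state space of group compositions.

A state records, for each of ``k`` equal-sized groups, how many agents of
each of ``T`` types it contains.  Per group the compositions are the weak
compositions of ``n`` into ``T`` parts, ``C(n+T-1, T-1)`` of them, so the
full space has ``C(n+T-1, T-1)**k`` states.  Enumeration order is
lexicographic on the flattened ``(group, type)`` count vector, which makes
indices reproducible across runs and versions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from math import comb

import numpy as np

__all__ = ["StateIndex", "count_states", "enumerate_states", "compositions"]

#: Refuse to materialize spaces larger than this by default.
DEFAULT_STATE_CAP = 10**6

ENUMERATION_ORDER = "lexicographic-flattened-counts"


def count_states(n: int, k: int, T: int) -> int:
    """Number of states for ``k`` equal groups of size ``n`` and ``T`` types."""
    if n < 1 or k < 1 or T < 1:
        raise ValueError("n, k and T must all be >= 1")
    return comb(n + T - 1, T - 1) ** k


def compositions(n: int, T: int) -> np.ndarray:
    """All weak compositions of ``n`` into ``T`` parts, lexicographic."""
    out = []

    def rec(prefix: list[int], remaining: int, parts: int) -> None:
        if parts == 1:
            out.append(prefix + [remaining])
            return
        for c in range(remaining + 1):
            rec(prefix + [c], remaining - c, parts - 1)

    rec([], n, T)
    return np.array(out, dtype=np.int64)


@dataclass
class StateIndex:
    """Bijective map between state indices and ``k x T`` count matrices."""

    n: int
    k: int
    T: int
    counts: np.ndarray  # (S, k, T)
    _lookup: dict[tuple[int, ...], int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self._lookup:
            flat = self.counts.reshape(len(self.counts), -1)
            self._lookup = {tuple(row): i for i, row in enumerate(flat.tolist())}

    def __len__(self) -> int:
        return len(self.counts)

    def state(self, index: int) -> np.ndarray:
        """Count matrix of the state at ``index``."""
        return self.counts[index]

    def index(self, state: np.ndarray) -> int:
        """Index of a ``k x T`` count matrix."""
        key = tuple(int(x) for x in np.asarray(state).ravel())
        try:
            return self._lookup[key]
        except KeyError:
            raise KeyError(f"not a valid state for (n={self.n}, k={self.k}, T={self.T}): {key}")


def enumerate_states(
    n: int, k: int, T: int, state_cap: int = DEFAULT_STATE_CAP
) -> StateIndex:
    """Materialize the full state space in lexicographic order.

    Raises ``ValueError`` if the space exceeds ``state_cap`` states; use
    :func:`count_states` for counting without enumeration.
    """
    total = count_states(n, k, T)
    if total > state_cap:
        raise ValueError(
            f"state space for (n={n}, k={k}, T={T}) has {total:,} states, "
            f"above the cap of {state_cap:,}; raise state_cap to force enumeration"
        )
    per_group = compositions(n, T)
    prod = product(range(len(per_group)), repeat=k)
    counts = np.array([[per_group[g] for g in combo] for combo in prod], dtype=np.int64)
    return StateIndex(n=n, k=k, T=T, counts=counts)
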