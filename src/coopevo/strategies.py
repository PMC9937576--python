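"""Strategy space for the agent-based simulator.

A strategy couples a stage-1 contribution action with a stage-2 helping
rule.  The helping rule is a pure predicate over what the donor can see
about the receiver: the receiver's stage-1 action, whether the receiver is
an in-group member, and (for history-conditioned rules) whether the
receiver extended help in the previous round.

The three core types are expressible here, and two named extras from the
wider strategy space are provided: the *nondiscriminating helper*, who
helps any stage-1 cooperator regardless of the kind of cooperation, and
the *second-order free-rider*, who contributes in stage 1 but never pays
the helping cost.  History-conditioned ("detecting") variants of the
helpers withhold help from receivers who did not help in the previous
round, which is what punishes second-order free-riding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import Action

__all__ = [
    "ExtendedStrategy",
    "ReceiverInfo",
    "StrategySpace",
    "helping_decision",
    "UNIVERSALIST",
    "PAROCHIALIST",
    "FREE_RIDER",
    "NONDISCRIMINATING_HELPER",
    "SECOND_ORDER_FREE_RIDER",
    "SECOND_ORDER_FREE_RIDER_CLUB",
    "DETECTING_UNIVERSALIST",
    "DETECTING_PAROCHIALIST",
    "core_space",
]

#: Helping-rule names -> integer codes used by the fast kernels.
RULES = ("never", "public", "club-ingroup", "any-cooperator")


@dataclass(frozen=True)
class ExtendedStrategy:
    """A (contribution action, helping rule) pair.

    ``conditional=True`` additionally requires that the receiver helped in
    the previous round (second-order reputation); what counts in round 1,
    when no history exists, is the caller's benefit-of-the-doubt choice.
    """

    name: str
    contribution: Action
    helping_rule: str
    conditional: bool = False

    def __post_init__(self) -> None:
        if self.helping_rule not in RULES:
            raise ValueError(f"unknown helping rule {self.helping_rule!r}")


@dataclass(frozen=True)
class ReceiverInfo:
    """What a donor observes about its assigned receiver."""

    action: Action
    in_group: bool
    helped_last_round: bool | None = None  # None: unknown (round 1)


def helping_decision(
    strategy: ExtendedStrategy, info: ReceiverInfo, benefit_of_doubt: bool = True
) -> bool:
    """Whether a donor of ``strategy`` helps a receiver described by ``info``.

    With an unknown helping history (round 1), ``benefit_of_doubt=True``
    treats the receiver as having helped.
    """
    rule = strategy.helping_rule
    if rule == "never":
        return False
    if rule == "public":
        base = info.action is Action.PUBLIC
    elif rule == "club-ingroup":
        base = info.action is Action.CLUB and info.in_group
    else:  # any-cooperator
        base = info.action in (Action.PUBLIC, Action.CLUB)
    if not base:
        return False
    if strategy.conditional:
        helped = info.helped_last_round
        if helped is None:
            helped = benefit_of_doubt
        return bool(helped)
    return True


UNIVERSALIST = ExtendedStrategy("U", Action.PUBLIC, "public")
PAROCHIALIST = ExtendedStrategy("P", Action.CLUB, "club-ingroup")
FREE_RIDER = ExtendedStrategy("F", Action.NONE, "never")
NONDISCRIMINATING_HELPER = ExtendedStrategy("ND", Action.PUBLIC, "any-cooperator")
SECOND_ORDER_FREE_RIDER = ExtendedStrategy("SF", Action.PUBLIC, "never")
SECOND_ORDER_FREE_RIDER_CLUB = ExtendedStrategy("SFc", Action.CLUB, "never")
DETECTING_UNIVERSALIST = ExtendedStrategy("Ud", Action.PUBLIC, "public", conditional=True)
DETECTING_PAROCHIALIST = ExtendedStrategy("Pd", Action.CLUB, "club-ingroup", conditional=True)

CORE_STRATEGIES = (UNIVERSALIST, PAROCHIALIST, FREE_RIDER)


class StrategySpace:
    """An ordered tuple of strategies with array-coded views for speed."""

    def __init__(self, strategies: tuple[ExtendedStrategy, ...] | list[ExtendedStrategy]):
        strategies = tuple(strategies)
        if len(strategies) == 0:
            raise ValueError("strategy space must be nonempty")
        if len({s.name for s in strategies}) != len(strategies):
            raise ValueError("strategy names must be unique")
        self.strategies = strategies
        action_code = {Action.NONE: 0, Action.CLUB: 1, Action.PUBLIC: 2}
        self.contrib_code = np.array(
            [action_code[s.contribution] for s in strategies], dtype=np.int64
        )
        self.rule_code = np.array(
            [RULES.index(s.helping_rule) for s in strategies], dtype=np.int64
        )
        self.conditional = np.array([s.conditional for s in strategies], dtype=np.bool_)
        self.is_helper = self.rule_code != 0

    def __len__(self) -> int:
        return len(self.strategies)

    def __iter__(self):
        return iter(self.strategies)

    def __getitem__(self, i: int) -> ExtendedStrategy:
        return self.strategies[i]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.strategies)

    @property
    def is_core3(self) -> bool:
        """True iff this is exactly (U, P, F) in canonical order."""
        return self.strategies == CORE_STRATEGIES


def core_space() -> StrategySpace:
    """The canonical three-type space (U, P, F)."""
    return StrategySpace(CORE_STRATEGIES)
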