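"""Model parameters for the nested club-good / public-good game.

The population consists of ``k`` groups of ``n`` agents each (``N = k*n``).
In stage 1 every agent receives an endowment ``e`` and may invest it in the
population-wide public good (benefit ``b_PG`` shared over all ``N`` agents),
in their own group's club good (benefit ``b_CG`` shared over the ``n`` group
members), or keep it.  In stage 2 each agent receives a second endowment and
meets a partner — an in-group member with probability ``p`` — whom they may
help at cost ``c_h``, conferring a benefit ``b_h``.

Both contribution options are social dilemmas: the marginal per-capita
return is below the cost (``b_CG/n < c_c`` and ``b_PG/N < c_c``) while the
total benefit created exceeds it (``c_c < b_CG < b_PG``).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

__all__ = ["ModelParams", "load_config", "save_config"]

#: Field order used for serialization.
_FIELDS = ("k", "n", "e", "c_c", "c_h", "b_CG", "b_PG", "b_h", "p", "mu")


@dataclass(frozen=True)
class ModelParams:
    """All game and evolution constants.

    Defaults are the baseline two-group configuration used throughout:
    ``k=2, n=4, e=c_c=c_h=1, b_CG=2, b_PG=3, mu=1e-4`` with the helping
    benefit ``b_h`` and boundary fluidity ``p`` as the canonically swept
    axes (defaults ``b_h=3``, ``p=0.5``).
    """

    k: int = 2
    n: int = 4
    e: float = 1.0
    c_c: float = 1.0
    c_h: float = 1.0
    b_CG: float = 2.0
    b_PG: float = 3.0
    b_h: float = 3.0
    p: float = 0.5
    mu: float = 1e-4

    def __post_init__(self) -> None:
        if int(self.k) != self.k or self.k < 1:
            raise ValueError(f"k must be a positive integer, got {self.k}")
        if int(self.n) != self.n or self.n < 1:
            raise ValueError(f"n must be a positive integer, got {self.n}")
        object.__setattr__(self, "k", int(self.k))
        object.__setattr__(self, "n", int(self.n))
        for name in ("e", "c_c", "c_h", "b_CG", "b_PG", "b_h"):
            v = getattr(self, name)
            if not (v >= 0):
                raise ValueError(f"{name} must be nonnegative, got {v}")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p must lie in [0, 1], got {self.p}")
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError(f"mu must lie in [0, 1], got {self.mu}")
        self._check_dilemma()

    def _check_dilemma(self) -> None:
        """Enforce the social-dilemma inequalities on both goods."""
        if not (self.b_CG / self.n < self.c_c):
            raise ValueError(
                f"club-good dilemma violated: b_CG/n = {self.b_CG / self.n:g} "
                f"must be < c_c = {self.c_c:g}"
            )
        if not (self.c_c < self.b_CG):
            raise ValueError(
                f"club-good dilemma violated: c_c = {self.c_c:g} "
                f"must be < b_CG = {self.b_CG:g}"
            )
        if not (self.b_PG / self.N < self.c_c):
            raise ValueError(
                f"public-good dilemma violated: b_PG/N = {self.b_PG / self.N:g} "
                f"must be < c_c = {self.c_c:g}"
            )
        if not (self.c_c < self.b_PG):
            raise ValueError(
                f"public-good dilemma violated: c_c = {self.c_c:g} "
                f"must be < b_PG = {self.b_PG:g}"
            )

    @property
    def N(self) -> int:
        """Total population size ``k * n``."""
        return self.k * self.n

    def replace(self, **changes: Any) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return {name: getattr(self, name) for name in _FIELDS}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ModelParams":
        unknown = set(d) - set(_FIELDS)
        if unknown:
            raise ValueError(f"unknown parameter field(s): {sorted(unknown)}")
        return cls(**dict(d))


def load_config(path: str | Path) -> ModelParams:
    """Load and validate a parameter set from a flat YAML/JSON config file.

    Missing fields fall back to the :class:`ModelParams` defaults.  The
    dilemma inequalities are enforced at load; a violation raises
    ``ValueError`` naming the specific inequality that failed.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text)
    else:
        import yaml

        data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ValueError(f"config {path} must be a flat key-value mapping")
    return ModelParams.from_dict(data)


def save_config(params: ModelParams, path: str | Path) -> None:
    """Write a parameter set to a flat YAML or JSON config file."""
    path = Path(path)
    d = params.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        import yaml

        path.write_text(yaml.safe_dump(d, sort_keys=False))
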