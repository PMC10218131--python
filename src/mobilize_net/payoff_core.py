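"""Payoff matrix of the mobilization-participation game.

The stage game is an asymmetric two-role game.  A social resource subject
(SRS) chooses positive or negative *participation*; a government resource
subject (GRS) chooses positive or negative *mobilization*.  The four cells
of the payoff matrix are

==============  ==============  ===========================  ======================
SRS strategy    GRS strategy    SRS gain                     GRS gain
==============  ==============  ===========================  ======================
positive        positive        pi_e - c_e + gamma           pi_g - c_g
negative        positive        pi_e - delta                 pi_g - c_g + beta*delta
positive        negative        pi_e - c_e                   -c_v
negative        negative        pi_e                         -c_v - c_s
==============  ==============  ===========================  ======================

Interventions enter only when the GRS mobilizes positively: a positive SRS
earns the reward ``gamma`` while a negative SRS pays the penalty ``delta``,
a fraction ``beta`` of which compensates the mobilizing GRS.
"""

from __future__ import annotations

import enum
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Mapping, NamedTuple, Union

import yaml

__all__ = ["Strategy", "GameParameters", "PairPayoff", "pair_payoff"]


class Strategy(enum.Enum):
    """Binary strategy label, role-agnostic.

    ``POSITIVE`` means positive mobilization for a GRS and positive
    participation for an SRS; likewise for ``NEGATIVE``.
    """

    POSITIVE = 1
    NEGATIVE = 0

    @classmethod
    def coerce(cls, value: Union["Strategy", str, int]) -> "Strategy":
        """Accept a Strategy, its name (any case), or its 0/1 value."""
        if isinstance(value, cls):
            return value
        if isinstance(value, str):
            try:
                return cls[value.upper()]
            except KeyError:
                raise ValueError(
                    f"invalid strategy label {value!r}: expected "
                    "'POSITIVE' or 'NEGATIVE'"
                ) from None
        if isinstance(value, (int, bool)) and value in (0, 1):
            return cls(int(value))
        raise ValueError(f"invalid strategy label {value!r}")


@dataclass(frozen=True)
class GameParameters:
    """The nine payoff parameters of the stage game (abstract payoff units).

    Parameters
    ----------
    pi_e
        Routine operating return of an SRS; accrues regardless of strategy.
    c_e
        Extra cost an SRS pays for positive participation (``c_e < pi_e``).
    pi_g
        Credibility gain of a GRS that mobilizes positively.
    c_g
        Organizational cost of positive mobilization.
    c_v
        Credibility loss of a GRS that mobilizes negatively.
    c_s
        Public-dissatisfaction cost added when both sides are negative.
    beta
        Fraction of the penalty ``delta`` recovered by a positive GRS
        facing a negative SRS (compensation rate).
    gamma
        Reward paid to a positive SRS facing a positive GRS.  ``0`` encodes
        "no reward".
    delta
        Penalty imposed on a negative SRS facing a positive GRS.  ``0``
        encodes "no penalty".
    """

    pi_e: float = 8.0
    c_e: float = 2.0
    pi_g: float = 3.0
    c_g: float = 5.0
    c_v: float = 1.0
    c_s: float = 2.0
    beta: float = 0.3
    gamma: float = 0.0
    delta: float = 0.0

    def __post_init__(self) -> None:
        if not self.pi_e > 0:
            raise ValueError(f"pi_e must be positive, got {self.pi_e}")
        if not self.pi_e > self.c_e:
            raise ValueError(
                f"pi_e must exceed c_e, got pi_e={self.pi_e}, c_e={self.c_e}"
            )
        for name in ("c_g", "c_v", "c_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("beta", "gamma", "delta"):
            if getattr(self, name) < 0:
                raise ValueError(
                    f"{name} must be non-negative, got {getattr(self, name)}"
                )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "GameParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown game parameter(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "GameParameters":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "GameParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def replace(self, **changes: float) -> "GameParameters":
        d = self.to_dict()
        d.update(changes)
        return GameParameters.from_dict(d)


class PairPayoff(NamedTuple):
    """Gains of the two sides of one SRS-GRS game (payoff units)."""

    srs_gain: float
    grs_gain: float


def pair_payoff(
    srs_strategy: Union[Strategy, str, int],
    grs_strategy: Union[Strategy, str, int],
    params: GameParameters,
) -> PairPayoff:
    """Payoff-matrix cell for one SRS-GRS pairing.

    Pure function of the two strategies and the parameters; see the module
    docstring for the four cells.
    """
    s = Strategy.coerce(srs_strategy)
    g = Strategy.coerce(grs_strategy)
    p = params
    if s is Strategy.POSITIVE and g is Strategy.POSITIVE:
        return PairPayoff(p.pi_e - p.c_e + p.gamma, p.pi_g - p.c_g)
    if s is Strategy.NEGATIVE and g is Strategy.POSITIVE:
        return PairPayoff(p.pi_e - p.delta, p.pi_g - p.c_g + p.beta * p.delta)
    if s is Strategy.POSITIVE and g is Strategy.NEGATIVE:
        return PairPayoff(p.pi_e - p.c_e, -p.c_v)
    return PairPayoff(p.pi_e, -p.c_v - p.c_s)
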