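"""The SF-6D health-state classification.

The SF-6D describes health on six dimensions — physical functioning, role
limitation, social functioning, pain, mental health and vitality — with
respectively 6, 4, 5, 6, 5 and 5 ordered levels (level 1 = no problems).
A health state is a choice of one level per dimension, written as a
6-digit code; there are 6*4*5*6*5*5 = 18,000 states.  Full health is
``111111`` and the "pits" (worst definable) state is ``645655``.

Utilities are modelled additively on indicator ("dummy") variables
``I_{dl}`` for every level l >= 2 of every dimension d (25 dummies), plus
one interaction term, MOST, switched on whenever any dimension sits at
one of its most-severe levels.  The predictor vector for a state is
therefore 26 binary entries; prepending an intercept column gives the
27-column design used by every model in this package.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DIMENSIONS",
    "LEVEL_BOUNDS",
    "MOST_SEVERE_LEVELS",
    "N_STATES",
    "N_DUMMIES",
    "N_PREDICTORS",
    "DUMMY_NAMES",
    "COEF_NAMES",
    "HealthState",
    "parse_state",
    "enumerate_states",
    "most_flag",
    "design_vector",
    "design_matrix",
]

DIMENSIONS: tuple[str, ...] = (
    "physical_functioning",
    "role_limitation",
    "social_functioning",
    "pain",
    "mental_health",
    "vitality",
)

#: Number of levels per dimension, in the order above.
LEVEL_BOUNDS: tuple[int, ...] = (6, 4, 5, 6, 5, 5)

#: Levels counting as "most severe" per dimension: 4-6 for physical
#: functioning, 3-4 for role limitation, 4-5 for social functioning,
#: 5-6 for pain, 4-5 for mental health and vitality.
MOST_SEVERE_LEVELS: tuple[frozenset[int], ...] = (
    frozenset({4, 5, 6}),
    frozenset({3, 4}),
    frozenset({4, 5}),
    frozenset({5, 6}),
    frozenset({4, 5}),
    frozenset({4, 5}),
)

N_STATES = 18000
N_DUMMIES = sum(b - 1 for b in LEVEL_BOUNDS)  # 25
N_PREDICTORS = N_DUMMIES + 1  # + MOST

_DIM_ABBREV = ("PF", "RL", "SF", "PAIN", "MH", "VT")

#: Dummy names, dimension-major and level-ascending: PF2..PF6, RL2..RL4,
#: SF2..SF5, PAIN2..PAIN6, MH2..MH5, VT2..VT5, then MOST.
DUMMY_NAMES: tuple[str, ...] = tuple(
    f"{abbr}{lvl}"
    for abbr, bound in zip(_DIM_ABBREV, LEVEL_BOUNDS)
    for lvl in range(2, bound + 1)
) + ("MOST",)

#: Coefficient layout used throughout: intercept followed by the 26 dummies.
COEF_NAMES: tuple[str, ...] = ("intercept",) + DUMMY_NAMES

# column offset of each dimension's first dummy (level 2) in the 26-vector
_DIM_OFFSETS = tuple(
    sum(b - 1 for b in LEVEL_BOUNDS[:d]) for d in range(len(LEVEL_BOUNDS))
)


@dataclass(frozen=True, order=True)
class HealthState:
    """An SF-6D health state: one level per dimension.

    Parameters
    ----------
    levels : tuple of 6 ints
        Level per dimension in the order ``DIMENSIONS``; each must lie in
        ``[1, bound]`` with bounds ``LEVEL_BOUNDS``.
    """

    levels: tuple[int, int, int, int, int, int]

    def __post_init__(self) -> None:
        levels = tuple(int(v) for v in self.levels)
        if len(levels) != 6:
            raise ValueError(f"expected 6 levels, got {len(levels)}")
        for dim, (lvl, bound) in enumerate(zip(levels, LEVEL_BOUNDS)):
            if not 1 <= lvl <= bound:
                raise ValueError(
                    f"level {lvl} out of range [1, {bound}] for dimension "
                    f"{DIMENSIONS[dim]!r}"
                )
        object.__setattr__(self, "levels", levels)

    @property
    def code(self) -> str:
        """6-digit string representation, e.g. ``'645655'``."""
        return "".join(str(v) for v in self.levels)

    @classmethod
    def from_code(cls, code: str) -> "HealthState":
        return parse_state(code)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.code


FULL_HEALTH = HealthState((1, 1, 1, 1, 1, 1))
PITS = HealthState((6, 4, 5, 6, 5, 5))


def parse_state(code: str) -> HealthState:
    """Parse a 6-digit state code into a :class:`HealthState`.

    Raises ``ValueError`` for non-digit input, wrong length, or a level
    outside its dimension's bound (e.g. role limitation level 5).
    """
    if not isinstance(code, str):
        raise TypeError(f"state code must be a string, got {type(code).__name__}")
    if len(code) != 6 or not code.isdigit():
        raise ValueError(f"state code must be exactly 6 digits, got {code!r}")
    return HealthState(tuple(int(c) for c in code))


def _all_states() -> tuple[HealthState, ...]:
    global _ALL_STATES_CACHE
    if _ALL_STATES_CACHE is None:
        _ALL_STATES_CACHE = tuple(
            HealthState(levels)
            for levels in itertools.product(
                *(range(1, b + 1) for b in LEVEL_BOUNDS)
            )
        )
    return _ALL_STATES_CACHE


_ALL_STATES_CACHE: tuple[HealthState, ...] | None = None


def enumerate_states() -> list[HealthState]:
    """All 18,000 valid states in lexicographic order of their codes."""
    return list(_all_states())


def most_flag(state: HealthState) -> int:
    """1 if any dimension is at a most-severe level, else 0."""
    return int(
        any(lvl in severe for lvl, severe in zip(state.levels, MOST_SEVERE_LEVELS))
    )


def design_vector(state: HealthState) -> np.ndarray:
    """26-entry predictor vector: 25 level dummies followed by MOST.

    Within each dimension at most one dummy is on (level >= 2); full
    health ``111111`` maps to the all-zero vector.
    """
    z = np.zeros(N_PREDICTORS)
    for dim, lvl in enumerate(state.levels):
        if lvl >= 2:
            z[_DIM_OFFSETS[dim] + (lvl - 2)] = 1.0
    z[N_DUMMIES] = most_flag(state)
    return z


def design_matrix(
    states: Iterable[HealthState | str], intercept: bool = True
) -> np.ndarray:
    """Stack design vectors for ``states``; optionally prepend an intercept
    column, giving the 27-column layout matching ``COEF_NAMES``."""
    rows = [
        design_vector(s if isinstance(s, HealthState) else parse_state(s))
        for s in states
    ]
    Z = np.asarray(rows, dtype=float).reshape(len(rows), N_PREDICTORS)
    if intercept:
        Z = np.column_stack([np.ones(len(rows)), Z])
    return Z


def as_state(state: HealthState | str | Sequence[int]) -> HealthState:
    """Coerce a code string, level sequence or HealthState to HealthState."""
    if isinstance(state, HealthState):
        return state
    if isinstance(state, str):
        return parse_state(state)
    return HealthState(tuple(state))
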