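"""EQ-5D-3L health states: parsing, enumeration, and derived regressors.

The EQ-5D-3L descriptive system records health along five dimensions --
mobility (M), self-care (S), usual activities (U), pain/discomfort (P) and
anxiety/depression (A) -- each at one of three levels: 1 (no problems),
2 (some problems), 3 (extreme problems).  A state is written as a five-digit
code in the fixed order M, S, U, P, A, so ``11111`` is perfect health and
``33333`` the worst describable state.  There are 3**5 = 243 states, of
which 242 have at least one impaired dimension.

The regressors derived here are the ones used by the US valuation model and
its constant-term re-expression:

* ten level dummies ``M2 .. A2`` and ``M3 .. A3``;
* ``I2`` / ``I3`` -- number of dimensions at level 2 / 3 beyond the first;
* ``I22`` / ``I32`` -- their squares;
* ``D1`` -- number of impaired dimensions beyond the first,
  ``max(n_impaired - 1, 0)``; the term the original model used in place of
  an intercept;
* ``N3`` -- indicator that any dimension is at level 3 (UK-model-style term).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, List

__all__ = [
    "DIMENSIONS",
    "DIMENSION_NAMES",
    "HealthState",
    "StateFeatures",
    "parse_state",
    "enumerate_states",
    "features",
    "impairment_group",
]

#: Single-letter dimension labels in canonical code order.
DIMENSIONS = ("M", "S", "U", "P", "A")

#: Full dimension names, same order as :data:`DIMENSIONS`.
DIMENSION_NAMES = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)

_VALID_LEVELS = frozenset({1, 2, 3})


@dataclass(frozen=True, order=True)
class HealthState:
    """One EQ-5D-3L health state; five levels, each in {1, 2, 3}."""

    mobility: int
    self_care: int
    usual_activities: int
    pain_discomfort: int
    anxiety_depression: int

    def __post_init__(self) -> None:
        for name, level in zip(DIMENSION_NAMES, self.levels):
            if level not in _VALID_LEVELS:
                raise ValueError(
                    f"invalid level {level!r} for dimension {name}: "
                    "levels must be 1, 2 or 3"
                )

    @property
    def levels(self) -> tuple[int, int, int, int, int]:
        return (
            self.mobility,
            self.self_care,
            self.usual_activities,
            self.pain_discomfort,
            self.anxiety_depression,
        )

    @property
    def code(self) -> str:
        """Five-digit code in M, S, U, P, A order (e.g. ``"33133"``)."""
        return "".join(str(level) for level in self.levels)

    @property
    def n_impaired(self) -> int:
        """Number of dimensions not at level 1."""
        return sum(1 for level in self.levels if level > 1)

    def is_perfect(self) -> bool:
        return self.n_impaired == 0

    def with_level(self, dimension: str, level: int) -> "HealthState":
        """Return a copy with one dimension moved to ``level``.

        ``dimension`` may be a canonical letter (``"U"``) or a full name
        (``"usual_activities"``).
        """
        idx = _dimension_index(dimension)
        levels = list(self.levels)
        levels[idx] = level
        return HealthState(*levels)

    def __str__(self) -> str:
        return self.code


def _dimension_index(dimension: str) -> int:
    key = dimension.strip()
    if key.upper() in DIMENSIONS:
        return DIMENSIONS.index(key.upper())
    if key.lower() in DIMENSION_NAMES:
        return DIMENSION_NAMES.index(key.lower())
    raise ValueError(
        f"unknown dimension {dimension!r}; expected one of "
        f"{DIMENSIONS} or {DIMENSION_NAMES}"
    )


@dataclass(frozen=True)
class StateFeatures:
    """Derived regressors for one health state."""

    n2: int
    n3: int
    M2: int
    S2: int
    U2: int
    P2: int
    A2: int
    M3: int
    S3: int
    U3: int
    P3: int
    A3: int
    I2: int
    I3: int
    I22: int
    I32: int
    D1: int
    N3: int

    @property
    def n_impaired(self) -> int:
        return self.n2 + self.n3

    def __getitem__(self, name: str) -> int:
        try:
            return getattr(self, name)
        except AttributeError:
            raise KeyError(name) from None


def parse_state(code: str) -> HealthState:
    """Parse a five-digit EQ-5D-3L code such as ``"33133"``.

    Raises
    ------
    ValueError
        If the code is not exactly five characters, or any character is
        outside {1, 2, 3}; the message names the offending position.
    """
    if not isinstance(code, str):
        raise TypeError(f"state code must be a string, got {type(code).__name__}")
    if len(code) != 5:
        raise ValueError(
            f"state code must have exactly 5 characters, got {len(code)} "
            f"in {code!r}"
        )
    levels = []
    for pos, char in enumerate(code, start=1):
        if char not in "123":
            raise ValueError(
                f"invalid level {char!r} at position {pos} "
                f"({DIMENSION_NAMES[pos - 1]}) in state code {code!r}: "
                "levels must be 1, 2 or 3"
            )
        levels.append(int(char))
    return HealthState(*levels)


def enumerate_states(include_perfect: bool = True) -> List[HealthState]:
    """All EQ-5D-3L states in lexicographic code order.

    243 states with ``include_perfect``, otherwise the 242 states having at
    least one dimension above level 1.
    """
    states = [HealthState(*levels) for levels in _all_level_tuples()]
    if not include_perfect:
        states = [s for s in states if not s.is_perfect()]
    return states


def _all_level_tuples() -> Iterator[tuple[int, ...]]:
    return itertools.product((1, 2, 3), repeat=5)


def features(state: HealthState) -> StateFeatures:
    """Compute the derived regressors for one state.

    For perfect health every feature is zero.  The identity
    ``D1 = I2 + I3 + 1{n2 > 0 and n3 > 0}`` holds for every state.
    """
    levels = state.levels
    n2 = sum(1 for lv in levels if lv == 2)
    n3 = sum(1 for lv in levels if lv == 3)
    dummies = {}
    for dim, lv in zip(DIMENSIONS, levels):
        dummies[f"{dim}2"] = int(lv == 2)
        dummies[f"{dim}3"] = int(lv == 3)
    i2 = max(n2 - 1, 0)
    i3 = max(n3 - 1, 0)
    return StateFeatures(
        n2=n2,
        n3=n3,
        I2=i2,
        I3=i3,
        I22=i2 * i2,
        I32=i3 * i3,
        D1=max(n2 + n3 - 1, 0),
        N3=int(n3 > 0),
        **dummies,
    )


def impairment_group(state: HealthState) -> str:
    """Group label by number of impaired dimensions.

    ``"perfect"`` (0), ``"one"`` (1), ``"two"`` (2) or ``"three_plus"``
    (3 or more).  Over the full 243-state space the group sizes are
    1 / 10 / 40 / 192.
    """
    n = state.n_impaired
    if n == 0:
        return "perfect"
    if n == 1:
        return "one"
    if n == 2:
        return "two"
    return "three_plus"
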