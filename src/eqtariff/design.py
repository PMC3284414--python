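"""Design matrices for the three tariff model specifications.

Three predictor sets are supported, all over the same ten level dummies:

``D1O``
    The original US specification: no intercept; the D1 term (impaired
    dimensions beyond the first) stands in for a constant.
``D1C``
    The mathematically equivalent constant-term re-expression: intercept
    plus the same predictors minus D1.
``D1C_N3``
    D1C with the I3 count replaced by the UK-style N3 dummy (any level-3
    problem present); predicts identically to D1C when refit.

Over the 242 impaired states the D1O columns obey the exact identity
``sum(level dummies) - D1 = 1``, i.e. the intercept of D1C lies inside the
column span of D1O -- the algebraic heart of the equivalence between the
two parameterizations, and the source of D1O's extreme collinearity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .states import HealthState, enumerate_states, features

__all__ = [
    "DUMMY_NAMES",
    "INTERCEPT",
    "ModelSpec",
    "D1O",
    "D1C",
    "D1C_N3",
    "SPECS",
    "get_spec",
    "DesignMatrix",
    "build_design",
]

#: The ten level dummies in canonical order: level 2 block then level 3 block.
DUMMY_NAMES = ("M2", "S2", "U2", "P2", "A2", "M3", "S3", "U3", "P3", "A3")

#: Column label used for the intercept, when a spec has one.
INTERCEPT = "const"


@dataclass(frozen=True)
class ModelSpec:
    """A named predictor set with or without an intercept."""

    name: str
    predictors: tuple[str, ...]
    intercept: bool

    def __post_init__(self) -> None:
        if len(set(self.predictors)) != len(self.predictors):
            raise ValueError(f"duplicate predictor names in spec {self.name!r}")
        if INTERCEPT in self.predictors:
            raise ValueError(
                f"{INTERCEPT!r} is reserved for the intercept column"
            )

    @property
    def columns(self) -> tuple[str, ...]:
        """All column labels, intercept first when present."""
        return ((INTERCEPT,) if self.intercept else ()) + self.predictors

    @property
    def n_params(self) -> int:
        return len(self.columns)


D1O = ModelSpec("D1O", DUMMY_NAMES + ("I3", "I22", "I32", "D1"), intercept=False)
D1C = ModelSpec("D1C", DUMMY_NAMES + ("I3", "I22", "I32"), intercept=True)
D1C_N3 = ModelSpec("D1C_N3", DUMMY_NAMES + ("N3", "I22", "I32"), intercept=True)

SPECS = {spec.name: spec for spec in (D1O, D1C, D1C_N3)}


def get_spec(name: "str | ModelSpec") -> ModelSpec:
    """Resolve a spec name (case-insensitive) or pass a spec through."""
    if isinstance(name, ModelSpec):
        return name
    try:
        return SPECS[name.upper()]
    except KeyError:
        raise ValueError(
            f"unknown model spec {name!r}; known specs: {sorted(SPECS)}"
        ) from None


@dataclass
class DesignMatrix:
    """A numeric design: rows are states, columns the spec's predictors."""

    spec: ModelSpec
    frame: pd.DataFrame = field(repr=False)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def state_codes(self) -> list[str]:
        return list(self.frame.index)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def column(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy(dtype=float)

    def drop_column(self, name: str) -> np.ndarray:
        """All columns except ``name``, as a float array."""
        return self.frame.drop(columns=name).to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index_label="state")

    def __len__(self) -> int:
        return len(self.frame)


def build_design(
    spec: "str | ModelSpec",
    states: "Sequence[HealthState] | None" = None,
) -> DesignMatrix:
    """Evaluate a spec's predictors over a state set.

    ``states`` defaults to the 242 impaired states, the definition space
    used for the collinearity analysis.  Row order follows the given state
    order; columns follow the spec, intercept first when present.
    """
    spec = get_spec(spec)
    if states is None:
        states = enumerate_states(include_perfect=False)
    states = list(states)
    if not states:
        raise ValueError("state list must be non-empty")
    # respondent-level data repeats the same few states many times: compute
    # each distinct state's row once
    cache: dict[str, list[int]] = {}
    rows = []
    for state in states:
        row = cache.get(state.code)
        if row is None:
            feat = features(state)
            row = [feat[name] for name in spec.predictors]
            if spec.intercept:
                row = [1] + row
            cache[state.code] = row
        rows.append(row)
    frame = pd.DataFrame(
        np.asarray(rows, dtype=int),
        index=pd.Index([s.code for s in states], name="state"),
        columns=list(spec.columns),
    )
    return DesignMatrix(spec=spec, frame=frame)


def design_row(spec: "str | ModelSpec", state: HealthState) -> np.ndarray:
    """A single state's design row (intercept included when in spec)."""
    spec = get_spec(spec)
    feat = features(state)
    row = [feat[name] for name in spec.predictors]
    if spec.intercept:
        row = [1] + row
    return np.asarray(row, dtype=float)
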