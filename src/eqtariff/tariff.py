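"""Tariff scoring, exact re-parameterization, step counting, tied states.

A tariff maps every EQ-5D-3L state to a utility on the QALY scale anchored
at 1 (perfect health, state 11111) and 0 (death).  Coefficients live on the
signed "add to 1" scale: predicted utility = 1 + sum(coef * predictor), so
level dummies carry negative coefficients and the D1 term a positive one.
State 11111 is axiomatic: its value is 1 by definition of the scale, it is
outside the prediction scope, and the intercept of a constant-term tariff
is a constant over the 242 impaired states only.

The published US D1 coefficients (3-decimal precision) ship as
:data:`US_D1O_TARIFF`.  The two parameterizations are linked by an exact
linear re-parameterization: constant = -(D1 coefficient), each level dummy
shifted by the D1 coefficient, I3/I22/I32 untouched.  Because the shift is
exact, the two tariffs value every state identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import pandas as pd

from .design import D1C, D1O, DUMMY_NAMES, INTERCEPT, ModelSpec, get_spec
from .states import HealthState, enumerate_states, features, parse_state

__all__ = [
    "Tariff",
    "US_D1O_TARIFF",
    "predict_value",
    "predict_all",
    "reparameterize",
    "inverse_reparameterize",
    "count_steps",
    "find_tied_pairs",
    "TIE_TOLERANCE",
]

#: Half of the printed 3-decimal coefficient precision: two states whose
#: values differ by less than this are reported as tied.
TIE_TOLERANCE = 5e-4


@dataclass(frozen=True)
class Tariff:
    """A model spec plus one coefficient per column (incl. intercept)."""

    spec: ModelSpec
    coefficients: Mapping[str, float]
    standard_errors: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        expected = set(self.spec.columns)
        got = set(self.coefficients)
        missing = expected - got
        extra = got - expected
        if missing:
            raise ValueError(
                f"tariff for spec {self.spec.name} is missing coefficients "
                f"for: {sorted(missing)}"
            )
        if extra:
            raise ValueError(
                f"tariff for spec {self.spec.name} has coefficients for "
                f"unknown predictors: {sorted(extra)}"
            )
        if self.standard_errors is not None:
            bad = set(self.standard_errors) - expected
            if bad:
                raise ValueError(f"standard errors for unknown terms: {sorted(bad)}")
        object.__setattr__(self, "coefficients", dict(self.coefficients))
        if self.standard_errors is not None:
            object.__setattr__(
                self, "standard_errors", dict(self.standard_errors)
            )

    def coef(self, name: str) -> float:
        try:
            return self.coefficients[name]
        except KeyError:
            raise KeyError(
                f"tariff has no coefficient for predictor {name!r}"
            ) from None

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        out = {
            "spec": self.spec.name,
            "coefficients": dict(self.coefficients),
        }
        if self.standard_errors is not None:
            out["standard_errors"] = dict(self.standard_errors)
        return out

    @classmethod
    def from_dict(cls, data: Mapping) -> "Tariff":
        spec = get_spec(data["spec"])
        return cls(
            spec=spec,
            coefficients=data["coefficients"],
            standard_errors=data.get("standard_errors"),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "Tariff":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


#: The published US D1 tariff at printed (3-decimal) precision.
US_D1O_TARIFF = Tariff(
    spec=D1O,
    coefficients={
        "M2": -0.146, "S2": -0.175, "U2": -0.140, "P2": -0.173, "A2": -0.156,
        "M3": -0.558, "S3": -0.471, "U3": -0.374, "P3": -0.537, "A3": -0.450,
        "I3": 0.122, "I22": -0.011, "I32": 0.015,
        "D1": 0.140,
    },
    standard_errors={
        "M2": 0.008, "S2": 0.008, "U2": 0.008, "P2": 0.008, "A2": 0.008,
        "M3": 0.016, "S3": 0.016, "U3": 0.013, "P3": 0.020, "A3": 0.015,
        "I3": 0.018, "I22": 0.002, "I32": 0.003,
        "D1": 0.010,
    },
)


def _as_state(state: "HealthState | str") -> HealthState:
    return state if isinstance(state, HealthState) else parse_state(state)


def predict_value(tariff: Tariff, state: "HealthState | str") -> float:
    """Predicted utility of a state: 1 + sum of coefficient * predictor.

    State 11111 returns exactly 1.0: the scale anchors it axiomatically and
    the intercept (if any) is out of scope for it.
    """
    state = _as_state(state)
    if state.is_perfect():
        return 1.0
    feat = features(state)
    value = 1.0
    if tariff.spec.intercept:
        value += tariff.coef(INTERCEPT)
    for name in tariff.spec.predictors:
        x = feat[name]
        if x:
            value += tariff.coef(name) * x
    return value


def predict_all(
    tariff: Tariff, include_perfect: bool = True
) -> pd.Series:
    """Utilities for every state, indexed by code in lexicographic order."""
    states = enumerate_states(include_perfect=include_perfect)
    return pd.Series(
        [predict_value(tariff, s) for s in states],
        index=pd.Index([s.code for s in states], name="state"),
        name="utility",
    )


def reparameterize(tariff: Tariff) -> Tariff:
    """Exact D1O -> D1C re-expression.

    constant = -(D1 coefficient); each of the ten level dummies is shifted
    by the D1 coefficient; I3, I22, I32 carry over; D1 is dropped.  Values
    of all 243 states are unchanged.
    """
    if tariff.spec.name != "D1O":
        raise ValueError(
            f"reparameterize expects a D1O tariff, got spec {tariff.spec.name}"
        )
    d1 = tariff.coef("D1")
    coefs = {INTERCEPT: -d1}
    for name in DUMMY_NAMES:
        coefs[name] = tariff.coef(name) + d1
    for name in ("I3", "I22", "I32"):
        coefs[name] = tariff.coef(name)
    return Tariff(spec=D1C, coefficients=coefs)


def inverse_reparameterize(tariff: Tariff) -> Tariff:
    """Exact D1C -> D1O re-expression (inverse of :func:`reparameterize`)."""
    if tariff.spec.name != "D1C":
        raise ValueError(
            f"inverse_reparameterize expects a D1C tariff, got spec "
            f"{tariff.spec.name}"
        )
    const = tariff.coef(INTERCEPT)
    coefs = {"D1": -const}
    for name in DUMMY_NAMES:
        coefs[name] = tariff.coef(name) + const
    for name in ("I3", "I22", "I32"):
        coefs[name] = tariff.coef(name)
    return Tariff(spec=D1O, coefficients=coefs)


def count_steps(
    tariff: Tariff,
    state: "HealthState | str",
    start_point: str = "perfect_health",
) -> int:
    """Number of calculation steps to evaluate a tariff for one state.

    The counting rule: one step per invoked additive term (a predictor
    whose value is nonzero; the intercept counts as a term when in scope),
    plus one step per nontrivial multiplication (a predictor value other
    than 0 or 1).  Starting points:

    ``perfect_health``
        Evaluation starts from the anchor value 1; every invoked term is a
        step.
    ``any_impaired``
        Only meaningful for intercept tariffs: the constant is folded into
        the starting value (1 - constant, ".860 - disutility" for the
        published tariff), so it costs no step.
    """
    if start_point not in ("perfect_health", "any_impaired"):
        raise ValueError(f"unknown start_point {start_point!r}")
    if start_point == "any_impaired" and not tariff.spec.intercept:
        raise ValueError(
            "start_point='any_impaired' requires an intercept tariff; "
            f"spec {tariff.spec.name} has none"
        )
    state = _as_state(state)
    if state.is_perfect():
        return 0
    feat = features(state)
    steps = 0
    if tariff.spec.intercept and start_point == "perfect_health":
        steps += 1
    for name in tariff.spec.predictors:
        x = feat[name]
        if x != 0:
            steps += 1
            if x != 1:
                steps += 1
    return steps


def find_tied_pairs(
    tariff: Tariff,
    dimension: str = "usual_activities",
    from_level: int = 1,
    to_level: int = 2,
    forbid_level_2_elsewhere: bool = True,
    tolerance: float = TIE_TOLERANCE,
) -> list[tuple[str, str]]:
    """State pairs whose values coincide when one dimension moves level.

    Considers every pair ``(s, s')`` where ``s`` has ``dimension`` at
    ``from_level``, ``s'`` is ``s`` with that dimension at ``to_level``,
    and (by default) no other dimension sits at level 2 in either state.
    Returns the pairs whose predicted values agree within ``tolerance``,
    in lexicographic order of the first code.

    Under the published tariff, moving usual activities from 1 to 2 adds
    the U2 coefficient (-.140) and one unit of D1 (+.140): a wash for
    every start state except 11111, where D1 stays 0 and the full .140
    loss applies.  Hence 15 tied pairs out of 16 candidates.
    """
    from .states import DIMENSIONS, _dimension_index  # local: private helper

    idx = _dimension_index(dimension)
    pairs = []
    for state in enumerate_states(include_perfect=True):
        if state.levels[idx] != from_level:
            continue
        if forbid_level_2_elsewhere and any(
            lv == 2 for i, lv in enumerate(state.levels) if i != idx
        ):
            continue
        other = state.with_level(dimension, to_level)
        if abs(predict_value(tariff, state) - predict_value(tariff, other)) < tolerance:
            pairs.append(tuple(sorted((state.code, other.code))))
    return sorted(pairs)


def step_count_table(
    d1o: Tariff,
    d1c: Tariff,
    start_point: str = "perfect_health",
) -> pd.DataFrame:
    """Step counts for both tariffs over all 242 impaired states.

    Columns: impairment group, D1O steps, D1C steps, difference.  The
    ``any_impaired`` start applies only to the intercept tariff; the D1O
    count always starts from perfect health.
    """
    from .states import impairment_group

    rows = []
    for state in enumerate_states(include_perfect=False):
        steps_o = count_steps(d1o, state, "perfect_health")
        steps_c = count_steps(d1c, state, start_point)
        rows.append(
            {
                "state": state.code,
                "group": impairment_group(state),
                "steps_d1o": steps_o,
                "steps_d1c": steps_c,
                "difference": steps_o - steps_c,
            }
        )
    return pd.DataFrame(rows).set_index("state")
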