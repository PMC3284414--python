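"""Reference tables: tariff recalculation/VIF table and worked examples.

``recalculation_table`` lays the published D1-style tariff and its exact
constant-term re-expression side by side, with the computed VIF of every
predictor in both designs.  ``worked_examples_table`` shows the per-term
arithmetic for a set of example states under both parameterizations --
multiplier, contribution, and the resulting value sums.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .collinearity import vif_all
from .design import DUMMY_NAMES, INTERCEPT
from .states import features, parse_state
from .tariff import Tariff, US_D1O_TARIFF, predict_value, reparameterize

__all__ = ["recalculation_table", "worked_examples_table", "DEFAULT_EXAMPLE_STATES"]

#: Example states covering each calculation pattern: the anchor, an
#: all-level-2 state, and a tied pair differing in usual activities.
DEFAULT_EXAMPLE_STATES = ("11111", "22222", "33133", "33233")

_TERM_ORDER = (INTERCEPT, "D1") + DUMMY_NAMES + ("I3", "I22", "I32")


def recalculation_table(tariff: Tariff = US_D1O_TARIFF) -> pd.DataFrame:
    """D1O coefficients, both VIF columns, and the derived D1C coefficients.

    One row per term (constant first, then D1, dummies, I3, I22, I32);
    VIFs are computed over the 242 impaired states under each design's own
    convention.  Terms absent from a design get NaN.
    """
    if tariff.spec.name != "D1O":
        raise ValueError("recalculation table expects a D1O tariff")
    d1c = reparameterize(tariff)
    vif_o = vif_all("D1O")
    vif_c = vif_all("D1C")
    d1 = tariff.coef("D1")

    rows = []
    for term in _TERM_ORDER:
        in_o = term in tariff.spec.columns
        in_c = term in d1c.spec.columns
        if term == INTERCEPT:
            recalc = "-D1"
        elif term == "D1":
            recalc = "D1-D1"
        elif term in DUMMY_NAMES:
            recalc = f"{term}+D1"
        else:
            recalc = term
        rows.append(
            {
                "term": term,
                "d1o_coef": tariff.coef(term) if in_o else np.nan,
                "d1o_vif": vif_o.vif(term) if in_o and term != INTERCEPT else np.nan,
                "recalculation": recalc,
                "d1c_coef": d1c.coef(term) if in_c else np.nan,
                "d1c_vif": vif_c.vif(term) if in_c and term != INTERCEPT else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("term")


def worked_examples_table(
    tariff: Tariff = US_D1O_TARIFF,
    states: Sequence[str] = DEFAULT_EXAMPLE_STATES,
) -> pd.DataFrame:
    """Per-term contributions and value sums for example states.

    For each state: the predictor multiplier, the D1O contribution
    (coefficient x multiplier) and the D1C contribution.  The final
    ``sum`` row adds the perfect-health anchor 1 to all contributions and
    equals the predicted value under either parameterization.
    """
    if tariff.spec.name != "D1O":
        raise ValueError("worked examples expect a D1O tariff")
    d1c = reparameterize(tariff)

    columns: dict[str, list] = {}
    index = ["perfect_health", *(t for t in _TERM_ORDER), "sum"]
    for code in states:
        state = parse_state(code)
        feat = features(state)
        perfect = state.is_perfect()
        mult, contrib_o, contrib_c = [1.0], [np.nan], [np.nan]
        for term in _TERM_ORDER:
            if term == INTERCEPT:
                x = 0 if perfect else 1
                mult.append(x)
                contrib_o.append(np.nan)
                contrib_c.append(d1c.coef(term) * x if x else 0.0)
                continue
            x = feat[term]
            mult.append(x)
            contrib_o.append(tariff.coef(term) * x)
            contrib_c.append(d1c.coef(term) * x if term != "D1" else np.nan)
        mult.append(np.nan)
        contrib_o.append(predict_value(tariff, state))
        contrib_c.append(predict_value(d1c, state))
        columns[f"{code}_multiplier"] = mult
        columns[f"{code}_d1o"] = contrib_o
        columns[f"{code}_d1c"] = contrib_c
    # perfect-health anchor row carries the starting value 1 for both models
    table = pd.DataFrame(columns, index=pd.Index(index, name="term"))
    for code in states:
        table.loc["perfect_health", f"{code}_d1o"] = 1.0
        table.loc["perfect_health", f"{code}_d1c"] = 1.0
    return table
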