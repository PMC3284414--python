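"""Variance inflation factors over the 242-state design space.

A predictor's VIF is 1/(1 - R^2), where R^2 comes from regressing that
predictor on all the other predictors of the model.  sqrt(VIF) measures how
much the predictor's coefficient SE is inflated relative to a design in
which it were uncorrelated with the rest.  Here the "data" are not survey
responses but the design space itself: every one of the 242 impaired
EQ-5D-3L states enters once with equal weight, so the VIFs are exact
combinatorial quantities, not estimates.

Conventions.  For an intercept model the auxiliary regression includes the
intercept and R^2 is the usual centered one.  For the intercept-free D1O
design the centered-with-intercept auxiliary regression is degenerate: the
exact identity sum(dummies) - D1 = 1 puts the constant inside the column
span, so every dummy would have R^2 = 1 and an infinite VIF.  The finite
VIFs conventionally reported for that model (and reproduced here, e.g.
113.184 for D1) come from the auxiliary regression over the model's own
columns only, with uncentered R^2 = 1 - SSR / sum(y^2) -- the convention
standard software applies to no-intercept models.  ``convention="match_model"``
(the default) picks centered/uncentered according to whether the model has
an intercept; both can also be forced explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .design import DesignMatrix, INTERCEPT, ModelSpec, build_design, get_spec
from .states import HealthState

__all__ = [
    "VIFReport",
    "aux_r2",
    "vif_from_r2",
    "vif_all",
    "vif_oracle",
    "compare_reports",
]

#: Auxiliary R^2 beyond this is reported as an infinite VIF.
SINGULARITY_THRESHOLD = 1.0 - 1e-12

Convention = Literal["match_model", "centered", "uncentered"]


@dataclass
class VIFReport:
    """Per-predictor auxiliary R^2 and VIF for one model spec."""

    spec_name: str
    table: pd.DataFrame  # index: predictor; columns: r_squared, vif
    n_states: int
    convention: str

    def vif(self, predictor: str) -> float:
        return float(self.table.loc[predictor, "vif"])

    def r_squared(self, predictor: str) -> float:
        return float(self.table.loc[predictor, "r_squared"])

    @property
    def predictors(self) -> list[str]:
        return list(self.table.index)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="predictor")


def _resolve_centering(spec: ModelSpec, convention: Convention) -> bool:
    if convention == "match_model":
        return spec.intercept
    if convention == "centered":
        return True
    if convention == "uncentered":
        return False
    raise ValueError(f"unknown VIF convention {convention!r}")


def aux_r2(
    design: DesignMatrix,
    predictor: str,
    convention: Convention = "match_model",
) -> float:
    """R^2 of the auxiliary regression of one predictor on all others.

    The "others" are the model's remaining columns exactly as designed --
    the intercept participates whenever the model has one.  The convention
    controls the R^2 normalization: ``"centered"`` uses the total sum of
    squares about the mean (and adds an intercept to the auxiliary
    regression if the model lacks one, so the R^2 is well defined);
    ``"uncentered"`` normalizes by the raw sum of squares, the quantity the
    coefficient-SE algebra of an intercept-free model is built on.  A
    perfectly collinear predictor yields R^2 = 1 (and an infinite VIF
    downstream) rather than an error.
    """
    if predictor == INTERCEPT:
        raise ValueError("the intercept has no VIF; pick a real predictor")
    if predictor not in design.columns:
        raise ValueError(
            f"predictor {predictor!r} not in design columns {design.columns}"
        )
    centered = _resolve_centering(design.spec, convention)
    y = design.column(predictor)
    others = design.frame.drop(columns=[predictor])
    if centered and INTERCEPT not in others.columns:
        others = others.copy()
        others.insert(0, INTERCEPT, 1.0)
    if others.shape[1] == 0:
        raise ValueError("auxiliary regression needs at least one other column")
    A = others.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    ss_res = float(resid @ resid)
    if centered:
        ss_tot = float(((y - y.mean()) ** 2).sum())
    else:
        ss_tot = float((y**2).sum())
    if ss_tot == 0.0:
        return 1.0
    r2 = 1.0 - ss_res / ss_tot
    return min(max(r2, 0.0), 1.0)


def vif_from_r2(r2: float) -> float:
    """VIF = 1/(1 - R^2); infinite past the singularity threshold."""
    if r2 >= SINGULARITY_THRESHOLD:
        return math.inf
    return 1.0 / (1.0 - r2)


def vif_all(
    spec: "str | ModelSpec",
    states: "Optional[Sequence[HealthState]]" = None,
    convention: Convention = "match_model",
) -> VIFReport:
    """VIF for every non-intercept predictor of a spec.

    Defaults to the 242 impaired states with equal weight per state --
    the definition space of the tariff, not any survey sample.
    """
    spec = get_spec(spec)
    design = build_design(spec, states)
    rows = {}
    for name in spec.predictors:
        r2 = aux_r2(design, name, convention=convention)
        rows[name] = {"r_squared": r2, "vif": vif_from_r2(r2)}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "predictor"
    return VIFReport(
        spec_name=spec.name,
        table=table,
        n_states=len(design),
        convention=convention,
    )


def vif_oracle(
    design: DesignMatrix,
    convention: Convention = "match_model",
) -> pd.Series:
    """VIFs via the inverse (co)correlation matrix diagonal.

    Independent of the auxiliary-regression route: for the centered
    convention, the diagonal of the inverse Pearson correlation matrix of
    the non-intercept columns; for the uncentered one, the diagonal of the
    inverse cosine-similarity matrix X'X normalized by column norms, with
    the intercept column (when the model has one) kept in the matrix as a
    regular column.  Exact collinearity (a singular matrix) is reported as
    infinite VIFs.
    """
    centered = _resolve_centering(design.spec, convention)
    frame = design.frame
    if centered:
        frame = frame.drop(columns=[INTERCEPT], errors="ignore")
    names = list(frame.columns)
    X = frame.to_numpy(dtype=float)
    if centered:
        X = X - X.mean(axis=0)
    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0):
        raise ValueError("constant column has no correlation structure")
    R = (X / norms).T @ (X / norms)
    # exact symmetry for the permutation-symmetry property tests
    R = (R + R.T) / 2.0
    if np.linalg.matrix_rank(R, tol=1e-10) < R.shape[0]:
        diag = np.full(len(names), math.inf)
    else:
        diag = np.diag(np.linalg.inv(R))
    out = pd.Series(diag, index=pd.Index(names, name="predictor"), name="vif")
    return out.drop(index=INTERCEPT, errors="ignore")


def compare_reports(a: VIFReport, b: VIFReport) -> pd.DataFrame:
    """Side-by-side VIFs for the predictors two reports share."""
    shared = [p for p in a.predictors if p in set(b.predictors)]
    if not shared:
        raise ValueError(
            f"reports for {a.spec_name} and {b.spec_name} share no predictors"
        )
    col_a = f"vif_{a.spec_name}"
    col_b = f"vif_{b.spec_name}"
    if col_a == col_b:
        col_a, col_b = f"{col_a}_a", f"{col_b}_b"
    table = pd.DataFrame(
        {
            col_a: [a.vif(p) for p in shared],
            col_b: [b.vif(p) for p in shared],
        },
        index=pd.Index(shared, name="predictor"),
    )
    table["ratio"] = table[col_a] / table[col_b]
    return table
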