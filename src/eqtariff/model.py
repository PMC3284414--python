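"""OLS disutility model with results on the tariff coefficient scale.

The model regresses observed disutility (1 - TTO value) on the predictors
of a chosen spec -- with an intercept for D1C-style specs, without one for
D1O -- and reports everything back on the signed "add to 1" tariff scale
(utility = 1 + sum(coef * x)), so a fit converts directly to a
:class:`~eqtariff.tariff.Tariff`.  Disutility-scale OLS coefficients are
simply the negatives of tariff-scale ones; the coefficient covariance is
unaffected by the sign flip.

The two parameterizations span the same column space over any state set
containing states from at least two impairment groups, so their fits agree
on every fitted value, residual and R^2; only the coordinates (and hence
the individual coefficient SEs) differ.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg

from .design import INTERCEPT, ModelSpec, build_design, design_row, get_spec
from .states import HealthState, parse_state
from .tariff import Tariff

__all__ = ["DisutilityModel", "DisutilityResults"]


class DisutilityModel:
    """OLS of respondent disutility observations on a model spec's design."""

    def __init__(
        self,
        disutility: "Sequence[float] | np.ndarray | pd.Series",
        states: Sequence["HealthState | str"],
        spec: "str | ModelSpec",
    ):
        self.spec = get_spec(spec)
        self.states = [
            s if isinstance(s, HealthState) else parse_state(s) for s in states
        ]
        self.endog = np.asarray(disutility, dtype=float)
        if len(self.states) != self.endog.size:
            raise ValueError(
                f"{self.endog.size} disutility observations but "
                f"{len(self.states)} states"
            )
        design = build_design(self.spec, self.states)
        self.exog = pd.DataFrame(
            design.values, columns=design.columns, copy=False
        )
        self._check_rank()

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        spec: "str | ModelSpec",
        state_col: str = "state",
        disutility_col: str = "disutility",
    ) -> "DisutilityModel":
        """Build from a tidy frame with state-code and disutility columns."""
        for col in (state_col, disutility_col):
            if col not in data.columns:
                raise ValueError(f"data has no column {col!r}")
        return cls(
            disutility=data[disutility_col].to_numpy(dtype=float),
            states=list(data[state_col]),
            spec=spec,
        )

    def _check_rank(self) -> None:
        X = self.exog.to_numpy()
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # pivoted QR: the trailing pivots index the dependent columns
            _, _, piv = linalg.qr(X, mode="economic", pivoting=True)
            dependent = sorted(self.exog.columns[j] for j in piv[rank:])
            raise ValueError(
                f"design for spec {self.spec.name} is rank deficient "
                f"(rank {rank} < {X.shape[1]}); linearly dependent "
                f"columns: {dependent}"
            )

    def fit(self) -> "DisutilityResults":
        ols = sm.OLS(self.endog, self.exog)
        return DisutilityResults(self, ols.fit())


class DisutilityResults:
    """Fit results re-expressed on the tariff (utility) coefficient scale."""

    def __init__(self, model: DisutilityModel, sm_results):
        self.model = model
        self.spec = model.spec
        self._sm = sm_results

    # -- coefficient-scale quantities ----------------------------------

    @property
    def params(self) -> pd.Series:
        """Tariff-scale coefficients: negated disutility-scale OLS params."""
        return -self._sm.params

    @property
    def bse(self) -> pd.Series:
        return self._sm.bse

    def cov_params(self) -> pd.DataFrame:
        """Coefficient covariance (identical on either sign convention)."""
        return self._sm.cov_params()

    @property
    def tvalues(self) -> pd.Series:
        return -self._sm.tvalues

    @property
    def pvalues(self) -> pd.Series:
        return self._sm.pvalues

    # -- fit-level quantities ------------------------------------------

    @property
    def nobs(self) -> int:
        return int(self._sm.nobs)

    @property
    def rsquared(self) -> float:
        return float(self._sm.rsquared)

    @property
    def ssr(self) -> float:
        return float(self._sm.ssr)

    @property
    def resid(self) -> np.ndarray:
        return np.asarray(self._sm.resid)

    @property
    def fittedvalues(self) -> np.ndarray:
        """Fitted disutilities, one per observation."""
        return np.asarray(self._sm.fittedvalues)

    @property
    def scale(self) -> float:
        """Residual variance estimate."""
        return float(self._sm.scale)

    # -- conversions ----------------------------------------------------

    def to_tariff(self) -> Tariff:
        return Tariff(
            spec=self.spec,
            coefficients=self.params.to_dict(),
            standard_errors=self.bse.to_dict(),
        )

    def predict_utility(self, state: "HealthState | str") -> float:
        from .tariff import predict_value

        return predict_value(self.to_tariff(), state)

    def prediction_se(
        self, state: "HealthState | str", mode: str = "full_covariance"
    ) -> float:
        """SE of the predicted value of one state.

        ``full_covariance``: sqrt(x' Sigma x) with x the state's design row
        -- invariant under re-parameterization, so D1O and D1C fits of the
        same data agree for every state.  ``diagonal_only``: coefficient
        covariances ignored, sqrt(sum(x_j^2 Var_j)) -- the naive accounting
        under which the D1 term's SE enters a five-impairment state with
        multiplier 4 while a constant's enters once.  Perfect health has SE
        0: its value is axiomatic.
        """
        if mode not in ("full_covariance", "diagonal_only"):
            raise ValueError(f"unknown prediction SE mode {mode!r}")
        if isinstance(state, str):
            state = parse_state(state)
        if state.is_perfect():
            return 0.0
        x = design_row(self.spec, state)
        cov = self.cov_params().to_numpy()
        if mode == "full_covariance":
            var = float(x @ cov @ x)
        else:
            var = float((x**2) @ np.diag(cov))
        return float(np.sqrt(max(var, 0.0)))

    def summary(self) -> str:
        """Plain-text coefficient table on the tariff scale."""
        lines = [
            f"Disutility OLS fit  spec={self.spec.name}  "
            f"nobs={self.nobs}  R^2={self.rsquared:.6f}  "
            f"resid SD={np.sqrt(self.scale):.6f}",
            "",
            f"{'term':<8}{'coef':>10}{'SE':>10}{'t':>10}{'P>|t|':>10}",
        ]
        for name in self.spec.columns:
            lines.append(
                f"{name:<8}{self.params[name]:>10.4f}{self.bse[name]:>10.4f}"
                f"{self.tvalues[name]:>10.2f}{self.pvalues[name]:>10.4f}"
            )
        return "\n".join(lines)
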