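"""One-sample instrumental-variable estimation.

Observational OLS, two-stage least squares with a single allele-score
instrument, the Durbin-Wu-Hausman endogeneity test (control-function
form), and the bidirectional analysis that runs 2SLS in both causal
directions on one cohort.

The model objects follow a statsmodels-style pattern: construct from
arrays (or a DataFrame via ``from_dataframe``), then ``fit()`` returns an
:class:`~edumr.results.MRResult`.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .harmonize import AlleleScore, score_strength
from .results import MRResult

__all__ = [
    "ols_observational",
    "TwoStageLeastSquares",
    "durbin_wu_hausman",
    "bidirectional_mr",
]


def _as_array(v) -> np.ndarray:
    if isinstance(v, AlleleScore):
        return v.values
    return np.asarray(v, float)


def _covariate_matrix(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.empty((n, 0))
    C = np.asarray(covariates, float)
    if C.ndim == 1:
        C = C[:, None]
    return C


def ols_observational(
    y,
    x,
    covariates=None,
    exposure: str = "exposure",
    outcome: str = "outcome",
) -> MRResult:
    """Multiple linear regression of the outcome on the exposure.

    Returns the exposure slope with its conventional standard error and
    two-sided p-value, adjusted for the supplied covariates.
    """
    y = _as_array(y)
    x = _as_array(x)
    C = _covariate_matrix(covariates, len(y))
    design = sm.add_constant(np.column_stack([x, C]))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, design).fit()
    est, se = float(fit.params[1]), float(fit.bse[1])
    return MRResult(
        method="ols",
        exposure=exposure,
        outcome=outcome,
        estimate=est,
        se=se,
        p=float(fit.pvalues[1]),
        n=len(y),
    )


class TwoStageLeastSquares:
    """One-sample 2SLS with a single (allele-score) instrument.

    Stage 1 regresses the exposure on the instrument and covariates;
    stage 2 regresses the outcome on the fitted exposure and covariates.
    The reported standard error uses stage-2 residuals evaluated at the
    OBSERVED exposure (the standard 2SLS variance, not the naive
    OLS-on-fitted one).  Homoskedastic errors by default; ``robust=True``
    switches to the HC0 sandwich.
    """

    def __init__(
        self,
        y,
        x,
        instrument,
        covariates=None,
        exposure: str = "exposure",
        outcome: str = "outcome",
        robust: bool = False,
    ) -> None:
        self.y = _as_array(y)
        self.x = _as_array(x)
        self.z = _as_array(instrument)
        self.C = _covariate_matrix(covariates, len(self.y))
        if not (len(self.y) == len(self.x) == len(self.z) == self.C.shape[0]):
            raise ValueError("input lengths differ")
        self.exposure = exposure
        self.outcome = outcome
        self.robust = robust
        n, k = len(self.y), self.C.shape[1] + 2
        if n <= k + 1:
            raise ValueError("too few observations")
        if np.std(self.z) == 0:
            raise ValueError("instrument does not vary")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        outcome: str,
        exposure: str,
        instrument: str,
        covariates: Sequence[str] = (),
        **kw,
    ) -> "TwoStageLeastSquares":
        C = df[list(covariates)].to_numpy(float) if covariates else None
        return cls(
            df[outcome],
            df[exposure],
            df[instrument],
            covariates=C,
            exposure=exposure,
            outcome=outcome,
            **kw,
        )

    # -- internals --------------------------------------------------------

    def _design(self):
        n = len(self.y)
        Z = np.column_stack([np.ones(n), self.z, self.C])
        X = np.column_stack([np.ones(n), self.x, self.C])
        return Z, X

    def first_stage(self):
        """Stage-1 coefficients, fitted exposure, and residuals."""
        Z, _ = self._design()
        pi, *_ = np.linalg.lstsq(Z, self.x, rcond=None)
        xhat = Z @ pi
        return pi, xhat, self.x - xhat

    def fit(self, dwh: bool = False) -> MRResult:
        Z, X = self._design()
        n, k = X.shape
        partial_r2, f_stat = score_strength(
            self.z, self.x, self.C if self.C.shape[1] else None
        )
        if f_stat < 1e-6:
            raise ValueError("instrument unidentified (first-stage F ~ 0)")
        _, xhat, _ = self.first_stage()
        Xhat = np.column_stack([np.ones(n), xhat, self.C])
        beta, *_ = np.linalg.lstsq(Xhat, self.y, rcond=None)
        resid = self.y - X @ beta  # observed-exposure residuals
        xtx_inv = np.linalg.inv(Xhat.T @ Xhat)
        if self.robust:
            meat = Xhat.T @ (Xhat * resid[:, None] ** 2)
            cov = xtx_inv @ meat @ xtx_inv
        else:
            sigma2 = float(resid @ resid) / (n - k)
            cov = sigma2 * xtx_inv
        est, se = float(beta[1]), float(np.sqrt(cov[1, 1]))
        p = 2 * stats.norm.sf(abs(est) / se) if se > 0 else 0.0
        diagnostics = {}
        if dwh:
            stat, pdwh = durbin_wu_hausman(
                self.y, self.x, self.z, self.C if self.C.shape[1] else None
            )
            diagnostics = {"dwh_stat": stat, "dwh_p": pdwh}
        return MRResult(
            method="2sls",
            exposure=self.exposure,
            outcome=self.outcome,
            estimate=est,
            se=se,
            p=float(p),
            n=n,
            first_stage_F=f_stat,
            partial_r2=partial_r2,
            diagnostics=diagnostics,
        )


def durbin_wu_hausman(y, x, instrument, covariates=None) -> tuple[float, float]:
    """Durbin-Wu-Hausman endogeneity test, control-function form.

    Regresses the outcome on the exposure, covariates, and the first-stage
    residual; the squared t statistic of the residual term is the test
    statistic, with p-value from its F(1, df) reference distribution.
    """
    y = _as_array(y)
    x = _as_array(x)
    z = _as_array(instrument)
    C = _covariate_matrix(covariates, len(y))
    n = len(y)
    Z = np.column_stack([np.ones(n), z, C])
    pi, *_ = np.linalg.lstsq(Z, x, rcond=None)
    v = x - Z @ pi
    design = np.column_stack([np.ones(n), x, C, v])
    fit = sm.OLS(y, design).fit()
    # perfect fit (e.g. y identical to x): OLS and IV coincide exactly and
    # the residual-term t statistic is 0/0; report a zero statistic
    if fit.ssr <= 1e-12 * float(y @ y + 1.0):
        return 0.0, 1.0
    t_v = float(fit.tvalues[-1])
    stat = t_v**2
    p = float(stats.f.sf(stat, 1, fit.df_resid))
    return stat, p


def bidirectional_mr(
    cohort: pd.DataFrame,
    edu_score,
    myo_score,
    covariates: Sequence[str] = ("age", "sex"),
    edu_col: str = "edu_years",
    mse_col: str = "mse",
) -> tuple[MRResult, MRResult]:
    """Run 2SLS in both causal directions on one cohort.

    Direction 1: exposure = years of education, outcome = refractive
    error, instrument = education allele score.  Direction 2: exposure =
    refractive error, outcome = years of education, instrument = myopia
    allele score.  Each result carries first-stage strength and the
    Durbin-Wu-Hausman p-value in its diagnostics.
    """
    C = cohort[list(covariates)].to_numpy(float) if covariates else None
    e = _as_array(edu_score)
    m = _as_array(myo_score)
    fwd = TwoStageLeastSquares(
        cohort[mse_col], cohort[edu_col], e, covariates=C,
        exposure=edu_col, outcome=mse_col,
    ).fit(dwh=True)
    rev = TwoStageLeastSquares(
        cohort[edu_col], cohort[mse_col], m, covariates=C,
        exposure=mse_col, outcome=edu_col,
    ).fit(dwh=True)
    return fwd, rev
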