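"""Confounding and power diagnostics.

Instrument-confounder association scans (do the allele scores associate
with measured covariates?), confounding bias components comparing the
relative bias of the IV and OLS estimators, and statistical power for MR
via the non-centrality parameter of the IV test statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import brentq

__all__ = [
    "confounder_scan",
    "BiasComponents",
    "bias_components",
    "PowerSpec",
    "mr_power",
    "min_detectable_effect",
]


def _slope_p(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return float(fit.params[1]), float(fit.pvalues[1])


def confounder_scan(
    cohort: pd.DataFrame,
    scores: dict[str, np.ndarray],
    covariate_names: Sequence[str],
    exposure: str | None = None,
    outcome: str | None = None,
) -> pd.DataFrame:
    """Associations of each covariate with the allele scores, exposure and
    outcome (one row per covariate; slope and p per target).

    A covariate associated with an allele score violates the instrument's
    independence assumption; a covariate associated with exposure and
    outcome but not the score is the situation MR is robust to.
    """
    targets: dict[str, np.ndarray] = {
        name: np.asarray(getattr(s, "values", s), float) for name, s in scores.items()
    }
    if exposure is not None:
        targets[exposure] = cohort[exposure].to_numpy(float)
    if outcome is not None:
        targets[outcome] = cohort[outcome].to_numpy(float)

    rows = []
    for cov in covariate_names:
        c = cohort[cov].to_numpy(float)
        row: dict = {"covariate": cov}
        for tname, t in targets.items():
            slope, p = _slope_p(c, t)
            row[f"beta_{tname}"] = slope
            row[f"p_{tname}"] = p
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class BiasComponents:
    """Relative bias of OLS and IV estimators from one candidate confounder.

    In standardised (SD) units of the outcome per SD of exposure::

        bias_ols = r_cx * r_cy
        bias_iv  = (r_cz / r_zx) * r_cy

    where c = covariate, x = exposure, y = outcome, z = instrument.  A
    covariate uncorrelated with the instrument contributes no IV bias
    even when it confounds the observational estimate.
    """

    covariate: str
    r_cx: float
    r_cy: float
    r_cz: float
    r_zx: float
    bias_ols: float
    bias_iv: float


def bias_components(
    cohort: pd.DataFrame,
    score,
    covariate: str,
    exposure: str,
    outcome: str,
) -> BiasComponents:
    """Compute confounding bias-plot components for one covariate."""
    c = cohort[covariate].to_numpy(float)
    x = cohort[exposure].to_numpy(float)
    y = cohort[outcome].to_numpy(float)
    z = np.asarray(getattr(score, "values", score), float)
    r_cx = float(np.corrcoef(c, x)[0, 1])
    r_cy = float(np.corrcoef(c, y)[0, 1])
    r_cz = float(np.corrcoef(c, z)[0, 1])
    r_zx = float(np.corrcoef(z, x)[0, 1])
    if abs(r_zx) < 1e-6:
        raise ValueError("instrument uncorrelated with exposure (|r_zx| < 1e-6)")
    return BiasComponents(
        covariate=covariate,
        r_cx=r_cx,
        r_cy=r_cy,
        r_cz=r_cz,
        r_zx=r_zx,
        bias_ols=r_cx * r_cy,
        bias_iv=(r_cz / r_zx) * r_cy,
    )


@dataclass
class PowerSpec:
    """Inputs to the MR power calculation.

    ``r2_xz`` is the variance in the exposure explained by the
    instrument, ``beta`` the causal effect in outcome units per exposure
    unit, and ``sd_x``/``sd_y`` the marginal trait SDs (defaults 1, i.e.
    standardised effects).
    """

    n: int
    r2_xz: float
    beta: float
    alpha: float = 0.05
    sd_x: float = 1.0
    sd_y: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.r2_xz < 1):
            raise ValueError("r2_xz must lie in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.n < 1 or self.sd_x <= 0 or self.sd_y <= 0:
            raise ValueError("invalid sample size or trait SDs")


def mr_power(spec: PowerSpec) -> float:
    """Two-sided power of the IV test under the normal approximation.

    The non-centrality parameter is ``NCP = n * r2_xz * (beta*sd_x/sd_y)^2``
    and power = P(|Z + sqrt(NCP)| > z_{1-alpha/2}).  At ``beta = 0`` the
    power equals the type-I level exactly.
    """
    ncp = spec.n * spec.r2_xz * (spec.beta * spec.sd_x / spec.sd_y) ** 2
    z = stats.norm.ppf(1 - spec.alpha / 2)
    root = np.sqrt(ncp)
    return float(stats.norm.sf(z - root) + stats.norm.cdf(-z - root))


def min_detectable_effect(
    n: int,
    r2_xz: float,
    target_power: float = 0.8,
    alpha: float = 0.05,
    sd_x: float = 1.0,
    sd_y: float = 1.0,
) -> float:
    """Smallest |beta| detectable with the requested power, by bisection.

    Satisfies ``mr_power(min_detectable_effect(...)) == target_power`` to
    the bisection tolerance (1e-8 relative).
    """
    if not (alpha < target_power < 1):
        raise ValueError("target_power must lie in (alpha, 1)")

    def gap(beta: float) -> float:
        return mr_power(PowerSpec(n, r2_xz, beta, alpha, sd_x, sd_y)) - target_power

    hi = 1.0
    while gap(hi) < 0:
        hi *= 2
        if hi > 1e9:
            raise RuntimeError("failed to bracket the minimal detectable effect")
    return float(brentq(gap, 0.0, hi, rtol=1e-8))
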