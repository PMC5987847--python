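"""Two-sample summary-statistic MR estimators.

Pleiotropy-robust sensitivity estimators operating on per-variant
association summaries computed in non-overlapping samples: per-variant
Wald ratios, inverse-variance-weighted (IVW) regression through the
origin, MR-Egger regression with a directional-pleiotropy intercept, the
weighted median, and the kernel-based weighted mode.  The one-sample
cohort is turned into two non-overlapping samples by :func:`split_sample`
(exposure associations from one half, outcome associations from the
other), which makes the Egger regression valid.

Each estimator is a small model class whose ``fit()`` returns an
:class:`~edumr.results.MRResult`; thin functional wrappers are provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .results import MRResult

__all__ = [
    "SummaryStats",
    "split_sample",
    "wald_ratio",
    "IVW",
    "Egger",
    "WeightedMedian",
    "WeightedMode",
    "ivw",
    "egger",
    "weighted_median",
    "weighted_mode",
    "method_concordance",
]

_SS_COLUMNS = [
    "rsid", "ea", "oa", "beta_exp", "se_exp", "beta_out", "se_out", "n_exp", "n_out",
]


@dataclass
class SummaryStats:
    """Per-variant exposure and outcome associations from disjoint samples.

    ``exposure_sample`` and ``outcome_sample`` are provenance tags; the
    two-sample estimators refuse identical tags because MR-Egger is not
    valid when both association sets come from the same participants.
    """

    df: pd.DataFrame
    exposure: str = "exposure"
    outcome: str = "outcome"
    exposure_sample: str = "A"
    outcome_sample: str = "B"

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in _SS_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"summary stats missing columns: {missing}")
        if "valid" not in df.columns:
            df["valid"] = np.isfinite(df["beta_exp"]) & np.isfinite(df["beta_out"])
        df["valid"] &= (df["se_exp"] > 0) & (df["se_out"] > 0)
        self.df = df.reset_index(drop=True)
        if self.exposure_sample == self.outcome_sample:
            raise ValueError(
                "exposure and outcome associations must come from "
                "non-overlapping samples"
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def valid(self) -> pd.DataFrame:
        return self.df[self.df["valid"]]

    @classmethod
    def from_associations(
        cls,
        panel,
        assoc_exposure: pd.DataFrame,
        assoc_outcome: pd.DataFrame,
        **tags,
    ) -> "SummaryStats":
        """Assemble summary stats from two :func:`compute_gwas_summaries`
        outputs restricted to a panel's variants."""
        ae = assoc_exposure.set_index("rsid")
        ao = assoc_outcome.set_index("rsid")
        rows = panel.df[["rsid", "effect_allele", "other_allele"]].rename(
            columns={"effect_allele": "ea", "other_allele": "oa"}
        )
        df = rows.assign(
            beta_exp=ae.loc[rows["rsid"], "beta"].to_numpy(),
            se_exp=ae.loc[rows["rsid"], "se"].to_numpy(),
            beta_out=ao.loc[rows["rsid"], "beta"].to_numpy(),
            se_out=ao.loc[rows["rsid"], "se"].to_numpy(),
            n_exp=ae.loc[rows["rsid"], "n"].to_numpy(),
            n_out=ao.loc[rows["rsid"], "n"].to_numpy(),
        )
        return cls(df, **tags)

    @classmethod
    def from_tsv(cls, path: str | Path, **tags) -> "SummaryStats":
        return cls(pd.read_csv(path, sep="\t"), **tags)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def split_sample(
    cohort: pd.DataFrame, seed: int | np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Uniformly random disjoint halves of a cohort (sizes differ by <= 1).

    Group A carries the exposure associations and group B the outcome
    associations for direction 1; the roles swap for direction 2 so that
    no participant contributes to both sides of either fit.
    """
    n = len(cohort)
    if n < 4:
        raise ValueError("need at least 4 participants to split")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(n)
    half = n // 2
    a = cohort.iloc[np.sort(perm[:half])]
    b = cohort.iloc[np.sort(perm[half:])]
    return a, b


def wald_ratio(beta_zx, se_zx, beta_zy, se_zy) -> tuple[float, float]:
    """Single-variant causal estimate beta_zy / beta_zx with first-order
    delta-method SE ``se_zy / |beta_zx|``.

    Returns (nan, nan) when the variant-exposure association is zero
    (flagged invalid rather than raised).
    """
    if beta_zx == 0:
        return float("nan"), float("nan")
    return float(beta_zy / beta_zx), float(se_zy / abs(beta_zx))


def _ratios_and_weights(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    bx = df["beta_exp"].to_numpy(float)
    by = df["beta_out"].to_numpy(float)
    sy = df["se_out"].to_numpy(float)
    ratios = by / bx
    se_ratio = sy / np.abs(bx)
    weights = 1.0 / se_ratio**2
    return ratios, weights / weights.sum()


class _SummaryEstimator:
    """Base: validates inputs and exposes fit()."""

    min_variants = 1
    method = "summary"

    def __init__(self, ss: SummaryStats) -> None:
        self.ss = ss
        self.data = ss.valid[ss.valid["beta_exp"] != 0].reset_index(drop=True)
        if len(self.data) < self.min_variants:
            raise ValueError(
                f"{self.method} requires >= {self.min_variants} valid variants, "
                f"got {len(self.data)}"
            )

    def _result(self, est, se, p, **kw) -> MRResult:
        return MRResult(
            method=self.method,
            exposure=self.ss.exposure,
            outcome=self.ss.outcome,
            estimate=float(est),
            se=float(se),
            p=float(p),
            n=int(self.data["n_out"].max()),
            diagnostics={"n_variants": len(self.data), **kw.pop("diagnostics", {})},
            **kw,
        )


class IVW(_SummaryEstimator):
    """Fixed-effect inverse-variance-weighted estimator.

    Weighted regression of the outcome associations on the exposure
    associations through the origin with weights 1/se_out^2; reduces
    exactly to the Wald ratio for a single variant.
    """

    method = "ivw"
    min_variants = 1

    def fit(self) -> MRResult:
        d = self.data
        x = d["beta_exp"].to_numpy(float)
        y = d["beta_out"].to_numpy(float)
        w = 1.0 / d["se_out"].to_numpy(float) ** 2
        sxx = np.sum(w * x * x)
        est = np.sum(w * x * y) / sxx
        se = np.sqrt(1.0 / sxx)
        p = 2 * stats.norm.sf(abs(est) / se)
        return self._result(est, se, p)


class Egger(_SummaryEstimator):
    """MR-Egger: weighted regression WITH an intercept.

    Variants are oriented so every exposure association is non-negative;
    the slope estimates the causal effect (consistent under the InSIDE
    assumption) and the intercept estimates directional pleiotropy.
    Standard errors are multiplied by the residual scale factor
    ``max(1, sqrt(RSS_w / (L - 2)))``; p-values use the t(L-2) reference.
    """

    method = "egger"
    min_variants = 3

    def __init__(self, ss: SummaryStats, intercept: bool = True) -> None:
        super().__init__(ss)
        self.with_intercept = intercept

    def fit(self) -> MRResult:
        d = self.data
        flip = np.sign(d["beta_exp"].to_numpy(float))
        x = d["beta_exp"].to_numpy(float) * flip
        y = d["beta_out"].to_numpy(float) * flip
        w = 1.0 / d["se_out"].to_numpy(float) ** 2
        L = len(x)
        if not self.with_intercept:
            # constrained refit: regression through the origin == IVW slope
            sxx = np.sum(w * x * x)
            est = np.sum(w * x * y) / sxx
            se = np.sqrt(1.0 / sxx)
            p = 2 * stats.norm.sf(abs(est) / se)
            return self._result(est, se, p, diagnostics={"intercept_constrained": True})
        if np.ptp(x) < 1e-12 * max(np.abs(x).max(), 1.0):
            raise ValueError(
                "all exposure associations equal: Egger design collinear "
                "with the intercept (unidentifiable)"
            )
        X = np.column_stack([np.ones(L), x])
        XtW = X.T * w
        cov_unscaled = np.linalg.inv(XtW @ X)
        coef = cov_unscaled @ (XtW @ y)
        resid = y - X @ coef
        rss_w = float(np.sum(w * resid**2))
        scale = max(1.0, np.sqrt(rss_w / (L - 2)))
        se = np.sqrt(np.diag(cov_unscaled)) * scale
        df_resid = L - 2
        p_slope = 2 * stats.t.sf(abs(coef[1]) / se[1], df_resid)
        p_int = 2 * stats.t.sf(abs(coef[0]) / se[0], df_resid)
        return self._result(
            coef[1],
            se[1],
            p_slope,
            intercept={
                "estimate": float(coef[0]),
                "se": float(se[0]),
                "p": float(p_int),
            },
            diagnostics={"residual_scale": scale},
        )


def _bootstrap_se(ss_df: pd.DataFrame, estimator, n_boot: int, rng) -> float:
    """Parametric bootstrap: resample per-variant betas from their normal
    sampling distributions and re-estimate."""
    bx = ss_df["beta_exp"].to_numpy(float)
    by = ss_df["beta_out"].to_numpy(float)
    sx = ss_df["se_exp"].to_numpy(float)
    sy = ss_df["se_out"].to_numpy(float)
    ests = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        ests[b] = estimator(bx_b, by_b, sy)
    return float(np.std(ests, ddof=1))


def _weighted_median_point(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> float:
    ok = bx != 0
    ratios = by[ok] / bx[ok]
    w = (np.abs(bx[ok]) / sy[ok]) ** 2
    w = w / w.sum()
    order = np.argsort(ratios)
    r = ratios[order]
    w = w[order]
    cum = np.cumsum(w) - 0.5 * w  # mid-point cumulative weight
    return float(np.interp(0.5, cum, r))


class WeightedMedian(_SummaryEstimator):
    """Weighted median estimator (valid if >= 50% of weight is valid).

    Per-variant Wald ratios are ordered; the estimate is the ratio at
    which the inverse-variance cumulative weight crosses one half,
    linearly interpolated between adjacent ratios.  SE by seeded
    parametric bootstrap.
    """

    method = "weighted_median"
    min_variants = 3

    def __init__(self, ss: SummaryStats, n_boot: int = 1000, seed: int = 0) -> None:
        super().__init__(ss)
        self.n_boot = n_boot
        self.seed = seed

    def fit(self) -> MRResult:
        d = self.data
        est = _weighted_median_point(
            d["beta_exp"].to_numpy(float),
            d["beta_out"].to_numpy(float),
            d["se_out"].to_numpy(float),
        )
        rng = np.random.default_rng(self.seed)
        se = _bootstrap_se(d, _weighted_median_point, self.n_boot, rng)
        p = 2 * stats.norm.sf(abs(est) / se) if se > 0 else (0.0 if est else 1.0)
        return self._result(est, se, p, diagnostics={"n_boot": self.n_boot})


def _mode_bandwidth(ratios: np.ndarray, factor: float) -> float:
    """Modified Silverman rule on the ratio distribution."""
    L = len(ratios)
    sd = np.std(ratios, ddof=1) if L > 1 else 0.0
    mad = stats.median_abs_deviation(ratios, scale="normal")
    spread = min(x for x in (sd, mad) if x > 0) if max(sd, mad) > 0 else 0.0
    return factor * 0.9 * spread * L ** (-1 / 5)


def _weighted_mode_point(
    bx: np.ndarray, by: np.ndarray, sy: np.ndarray, factor: float = 1.0
) -> float:
    ok = bx != 0
    ratios = by[ok] / bx[ok]
    w = (np.abs(bx[ok]) / sy[ok]) ** 2
    w = w / w.sum()
    h = _mode_bandwidth(ratios, factor)
    if h <= 0:  # all ratios identical
        return float(ratios[0])
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 4096)
    dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2) @ w
    return float(grid[np.argmax(dens)])


class WeightedMode(_SummaryEstimator):
    """Weighted mode estimator (valid if the largest group of variants
    sharing one causal ratio is valid).

    A normal-kernel weighted density of the Wald ratios is maximised on a
    fine grid; the bandwidth is ``bandwidth_factor`` times the modified
    Silverman rule.  SE by seeded parametric bootstrap.
    """

    method = "weighted_mode"
    min_variants = 3

    def __init__(
        self,
        ss: SummaryStats,
        bandwidth_factor: float = 1.0,
        n_boot: int = 1000,
        seed: int = 0,
    ) -> None:
        super().__init__(ss)
        self.bandwidth_factor = bandwidth_factor
        self.n_boot = n_boot
        self.seed = seed

    def fit(self) -> MRResult:
        d = self.data
        point = lambda bx, by, sy: _weighted_mode_point(bx, by, sy, self.bandwidth_factor)
        est = point(
            d["beta_exp"].to_numpy(float),
            d["beta_out"].to_numpy(float),
            d["se_out"].to_numpy(float),
        )
        rng = np.random.default_rng(self.seed)
        se = _bootstrap_se(d, point, self.n_boot, rng)
        p = 2 * stats.norm.sf(abs(est) / se) if se > 0 else (0.0 if est else 1.0)
        return self._result(
            est, se, p,
            diagnostics={"n_boot": self.n_boot, "bandwidth_factor": self.bandwidth_factor},
        )


# -- functional wrappers --------------------------------------------------


def ivw(ss: SummaryStats) -> MRResult:
    return IVW(ss).fit()


def egger(ss: SummaryStats) -> MRResult:
    return Egger(ss).fit()


def weighted_median(ss: SummaryStats, n_boot: int = 1000, seed: int = 0) -> MRResult:
    return WeightedMedian(ss, n_boot=n_boot, seed=seed).fit()


def weighted_mode(
    ss: SummaryStats, bandwidth_factor: float = 1.0, n_boot: int = 1000, seed: int = 0
) -> MRResult:
    return WeightedMode(ss, bandwidth_factor=bandwidth_factor, n_boot=n_boot, seed=seed).fit()


def method_concordance(results: Sequence[MRResult]) -> dict:
    """Agreement report across estimators of the same exposure/outcome.

    Returns the range of point estimates, a sign-agreement flag, and the
    largest pairwise z-difference ``|b_i - b_j| / sqrt(se_i^2 + se_j^2)``.
    """
    if len(results) < 2:
        raise ValueError("need at least two results")
    pairs = {(r.exposure, r.outcome) for r in results}
    if len(pairs) != 1:
        raise ValueError(f"mixed exposure/outcome directions: {pairs}")
    est = np.array([r.estimate for r in results])
    se = np.array([r.se for r in results])
    zmax = 0.0
    for i in range(len(est)):
        for j in range(i + 1, len(est)):
            denom = np.sqrt(se[i] ** 2 + se[j] ** 2)
            if denom > 0:
                zmax = max(zmax, abs(est[i] - est[j]) / denom)
    signs = np.sign(est[est != 0])
    return {
        "methods": [r.method for r in results],
        "estimate_min": float(est.min()),
        "estimate_max": float(est.max()),
        "range": float(est.max() - est.min()),
        "sign_agreement": bool(len(signs) == 0 or np.all(signs == signs[0])),
        "max_pairwise_z": float(zmax),
    }
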