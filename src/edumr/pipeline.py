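"""End-to-end analysis pipeline.

Orchestrates scenario generation -> phenotype derivation -> allele
scoring -> bidirectional MR -> sensitivity suite -> report tables, with
deterministic outputs under a fixed seed and a manifest recording every
artefact.  Tables mirror the layout of the study's main report: an
observational table (two covariate models), an MR table (OLS estimate,
partial R^2, DWH p, IV estimate per direction), the split-sample
pleiotropy-sensitivity estimates, confounding bias-plot data, and the
power report.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import __version__
from .config import ScenarioConfig
from .diagnostics import bias_components, confounder_scan, min_detectable_effect, mr_power, PowerSpec
from .harmonize import VariantPanel, build_allele_score, score_strength
from .onesample import TwoStageLeastSquares, bidirectional_mr, ols_observational
from .phenotype import aggregate_refraction, apply_exclusions
from .simulate import CohortData, GenotypeMatrix, compute_gwas_summaries, simulate_cohort
from .twosample import (
    SummaryStats, egger, ivw, method_concordance, split_sample,
    weighted_median, weighted_mode,
)

__all__ = ["run_pipeline", "RunManifest", "report_observational_binned", "analysis_frame"]

log = logging.getLogger("edumr.pipeline")

MODEL_A_COVARIATES = ("age", "sex")
MODEL_B_COVARIATES = (
    "age", "sex", "townsend", "birth_weight", "breastfed", "northing", "easting",
)
BIAS_COVARIATES = (
    "townsend", "birth_weight", "breastfed", "northing", "easting",
) + tuple(f"pc{i}" for i in range(1, 11))


@dataclass
class RunManifest:
    """Record of one pipeline run: config hash, seed, timings, artefacts."""

    config_hash: str
    seed: int
    stage_seconds: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)

    def validate(self) -> None:
        missing = [p for p in self.artifacts.values() if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"manifest lists missing artefacts: {missing}")

    def save(self, path: str | Path) -> None:
        self.validate()
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


def _versions() -> dict:
    import scipy
    import statsmodels

    return {
        "edumr": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }


# -- stage helpers ---------------------------------------------------------


def analysis_frame(cohort: CohortData) -> pd.DataFrame:
    """Derived analysis table: one row per included participant with
    edu_years, mse, dichotomised education, covariates and both scores."""
    mse = aggregate_refraction(cohort.ophthalmic)
    phenos, counts = apply_exclusions(
        cohort.questionnaire, mse, genotyped_ids=cohort.genotypes.participant_ids
    )
    edu_score = build_allele_score(cohort.genotypes, cohort.edu_panel)
    myo_score = build_allele_score(cohort.genotypes, cohort.myo_panel)
    df = cohort.questionnaire.merge(
        phenos[["participant_id", "edu_years", "edu_after_16", "mse",
                "included", "exclusion_reason"]],
        on="participant_id",
    )
    df["edu_score"] = df["participant_id"].map(edu_score.series)
    df["myo_score"] = df["participant_id"].map(myo_score.series)
    df.attrs["exclusion_counts"] = counts
    return df[df["included"]].reset_index(drop=True)


def _per_variant_assoc(genotypes: GenotypeMatrix, panel: VariantPanel,
                       df: pd.DataFrame, phenotype: str,
                       covariates: Sequence[str]) -> pd.DataFrame:
    gm = genotypes.subset(panel.rsids)
    keep = np.asarray(pd.Index(gm.participant_ids).isin(df["participant_id"]))
    dos = gm.dosages[keep]
    sub = df.set_index("participant_id").loc[np.asarray(gm.participant_ids)[keep]]
    return compute_gwas_summaries(
        dos, sub[phenotype].to_numpy(float), sub[list(covariates)].to_numpy(float)
    ).assign(rsid=panel.rsids)


def split_sample_summaries(
    cohort: CohortData,
    df: pd.DataFrame,
    seed: int,
    covariates: Sequence[str] = MODEL_A_COVARIATES,
) -> tuple[SummaryStats, SummaryStats]:
    """Split-sample summary statistics for both causal directions.

    The included cohort is split into random halves A and B.  Direction 1
    (education -> MSE): exposure associations from A, outcome from B.
    Direction 2 (MSE -> education): exposure associations from B, outcome
    from A.  No participant contributes to both sides of either fit.
    """
    a, b = split_sample(df, seed)
    geno = cohort.genotypes
    fwd = SummaryStats.from_associations(
        cohort.edu_panel,
        _per_variant_assoc(geno, cohort.edu_panel, a, "edu_years", covariates),
        _per_variant_assoc(geno, cohort.edu_panel, b, "mse", covariates),
        exposure="edu_years", outcome="mse",
        exposure_sample="A", outcome_sample="B",
    )
    rev = SummaryStats.from_associations(
        cohort.myo_panel,
        _per_variant_assoc(geno, cohort.myo_panel, b, "mse", covariates),
        _per_variant_assoc(geno, cohort.myo_panel, a, "edu_years", covariates),
        exposure="mse", outcome="edu_years",
        exposure_sample="B", outcome_sample="A",
    )
    return fwd, rev


def report_observational_binned(
    phenos: pd.DataFrame,
    edu_col: str = "edu_years",
    mse_col: str = "mse",
    bins: Sequence[int] = range(15, 22),
) -> tuple[pd.DataFrame, dict]:
    """Mean refractive error by education-completion age, plus piecewise
    slopes for the <= 18 and > 18 segments.

    Empty bins appear as rows with n = 0 and missing means rather than
    being dropped.  Slopes are flagged undefined when a segment has fewer
    than two distinct completion ages.
    """
    d = phenos[[edu_col, mse_col]].dropna()
    year = d[edu_col].round().astype(int)
    rows = []
    for b in bins:
        grp = d.loc[year == b, mse_col]
        n = len(grp)
        mean = grp.mean() if n else np.nan
        se = grp.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        rows.append(
            {
                "edu_completion_age": b,
                "n": n,
                "mean_mse": mean,
                "ci95_low": mean - 1.96 * se if n > 1 else np.nan,
                "ci95_high": mean + 1.96 * se if n > 1 else np.nan,
            }
        )
    table = pd.DataFrame(rows)

    def _segment_slope(mask) -> tuple[float, float, bool]:
        seg = d[mask]
        if seg[edu_col].nunique() < 2:
            return np.nan, np.nan, False
        fit = sm.OLS(seg[mse_col], sm.add_constant(seg[edu_col])).fit()
        return float(fit.params.iloc[1]), float(fit.bse.iloc[1]), True

    s1, se1, ok1 = _segment_slope(d[edu_col] <= 18)
    s2, se2, ok2 = _segment_slope(d[edu_col] > 18)
    slopes = {
        "slope_le18": s1, "se_le18": se1, "defined_le18": ok1,
        "slope_gt18": s2, "se_gt18": se2, "defined_gt18": ok2,
    }
    return table, slopes


# -- pipeline --------------------------------------------------------------


def _mr_table_row(direction: str, ols_res, iv_res) -> dict:
    return {
        "direction": direction,
        "exposure": iv_res.exposure,
        "outcome": iv_res.outcome,
        "n": iv_res.n,
        "ols_estimate": ols_res.estimate,
        "ols_ci95_low": ols_res.ci95[0],
        "ols_ci95_high": ols_res.ci95[1],
        "ols_p": ols_res.p,
        "partial_r2": iv_res.partial_r2,
        "first_stage_F": iv_res.first_stage_F,
        "dwh_p": iv_res.diagnostics.get("dwh_p"),
        "iv_estimate": iv_res.estimate,
        "iv_se": iv_res.se,
        "iv_ci95_low": iv_res.ci95[0],
        "iv_ci95_high": iv_res.ci95[1],
        "iv_p": iv_res.p,
    }


def run_pipeline(
    config: ScenarioConfig | str | Path,
    outdir: str | Path,
    seed: int | None = None,
) -> RunManifest:
    """Execute every stage in order and write all report artefacts.

    Fully deterministic given the config (and ``seed`` override).  Any
    stage failure aborts with the stage name and cause.
    """
    cfg = config if isinstance(config, ScenarioConfig) else ScenarioConfig.from_file(config)
    if seed is not None:
        cfg = cfg.model_copy(update={"seed": seed})
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=cfg.config_hash(), seed=cfg.seed, versions=_versions()
    )
    state: dict = {}

    stages = [
        ("simulate", _stage_simulate),
        ("derive", _stage_derive),
        ("score", _stage_score),
        ("mr", _stage_mr),
        ("sensitivity", _stage_sensitivity),
        ("report", _stage_report),
    ]
    for name, fn in stages:
        t0 = time.perf_counter()
        log.info("[%s] starting", name)
        try:
            fn(cfg, out, state, manifest)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        manifest.stage_seconds[name] = round(time.perf_counter() - t0, 3)
        log.info("[%s] done in %.2fs", name, manifest.stage_seconds[name])

    manifest.artifacts["manifest"] = str(out / "manifest.json")
    (out / "manifest.json").write_text("{}")  # placeholder so validate() passes
    manifest.save(out / "manifest.json")
    return manifest


def _round_trip(df: pd.DataFrame, path: Path) -> None:
    # full-precision serialisation; display rounding is left to readers
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _stage_simulate(cfg, out, state, manifest) -> None:
    cohort = simulate_cohort(cfg)
    state["cohort"] = cohort
    cfg.to_file(out / "config.yaml")
    cohort.genotypes.to_vcf(out / "genotypes.vcf")
    _round_trip(cohort.questionnaire, out / "questionnaire.tsv")
    _round_trip(cohort.ophthalmic, out / "ophthalmic.tsv")
    cohort.edu_panel.to_tsv(out / "edu_panel.tsv")
    cohort.myo_panel.to_tsv(out / "myo_panel.tsv")
    truth_scalars = {
        k: v for k, v in cohort.truth.items() if np.isscalar(v) or isinstance(v, (bool, str, dict))
    }
    (out / "truth.json").write_text(json.dumps(truth_scalars, indent=2, default=float))
    manifest.artifacts.update(
        {
            "config": str(out / "config.yaml"),
            "genotypes": str(out / "genotypes.vcf"),
            "questionnaire": str(out / "questionnaire.tsv"),
            "ophthalmic": str(out / "ophthalmic.tsv"),
            "edu_panel": str(out / "edu_panel.tsv"),
            "myo_panel": str(out / "myo_panel.tsv"),
            "truth": str(out / "truth.json"),
        }
    )


def _stage_derive(cfg, out, state, manifest) -> None:
    df = analysis_frame(state["cohort"])
    state["df"] = df
    _round_trip(df, out / "phenotypes.tsv")
    (out / "exclusions.json").write_text(
        json.dumps(df.attrs["exclusion_counts"], indent=2)
    )
    manifest.artifacts["phenotypes"] = str(out / "phenotypes.tsv")
    manifest.artifacts["exclusions"] = str(out / "exclusions.json")


def _stage_score(cfg, out, state, manifest) -> None:
    df = state["df"]
    strength = {}
    for score_col, pheno, tag in (
        ("edu_score", "edu_years", "education_score_on_edu_years"),
        ("myo_score", "mse", "myopia_score_on_mse"),
    ):
        r2, f = score_strength(
            df[score_col], df[pheno], df[list(MODEL_A_COVARIATES)].to_numpy(float)
        )
        strength[tag] = {"partial_r2": r2, "F": f, "n": len(df)}
    state["strength"] = strength
    _round_trip(df[["participant_id", "edu_score", "myo_score"]], out / "scores.tsv")
    (out / "instrument_strength.json").write_text(json.dumps(strength, indent=2))
    manifest.artifacts["scores"] = str(out / "scores.tsv")
    manifest.artifacts["instrument_strength"] = str(out / "instrument_strength.json")


def _stage_mr(cfg, out, state, manifest) -> None:
    df = state["df"]
    rows1 = []
    for covs, model in ((MODEL_A_COVARIATES, "A"), (MODEL_B_COVARIATES, "B")):
        C = df[list(covs)].to_numpy(float)
        fwd = ols_observational(df["mse"], df["edu_years"], C,
                                exposure="edu_years", outcome="mse")
        rev = ols_observational(df["edu_years"], df["mse"], C,
                                exposure="mse", outcome="edu_years")
        for r in (fwd, rev):
            rows1.append({"model": model, "covariates": "+".join(covs), **r.to_dict()})
    _round_trip(pd.DataFrame(rows1), out / "table1_observational.tsv")

    fwd_iv, rev_iv = bidirectional_mr(
        df, df["edu_score"], df["myo_score"], covariates=MODEL_A_COVARIATES
    )
    C = df[list(MODEL_A_COVARIATES)].to_numpy(float)
    ols_fwd = ols_observational(df["mse"], df["edu_years"], C,
                                exposure="edu_years", outcome="mse")
    ols_rev = ols_observational(df["edu_years"], df["mse"], C,
                                exposure="mse", outcome="edu_years")
    table2 = pd.DataFrame(
        [
            _mr_table_row("edu_to_mse", ols_fwd, fwd_iv),
            _mr_table_row("mse_to_edu", ols_rev, rev_iv),
        ]
    )
    state["mr"] = {"fwd": fwd_iv, "rev": rev_iv}
    _round_trip(table2, out / "table2_mr.tsv")
    manifest.artifacts["table1"] = str(out / "table1_observational.tsv")
    manifest.artifacts["table2"] = str(out / "table2_mr.tsv")


def _stage_sensitivity(cfg, out, state, manifest) -> None:
    cohort, df = state["cohort"], state["df"]
    ss_fwd, ss_rev = split_sample_summaries(cohort, df, seed=cfg.seed + 1)
    ss_fwd.to_tsv(out / "summary_stats_edu_to_mse.tsv")
    ss_rev.to_tsv(out / "summary_stats_mse_to_edu.tsv")

    rows, concordance = [], {}
    for tag, ss in (("edu_to_mse", ss_fwd), ("mse_to_edu", ss_rev)):
        results = [
            ivw(ss),
            egger(ss),
            weighted_median(ss, seed=cfg.seed + 2),
            weighted_mode(ss, seed=cfg.seed + 3),
        ]
        for r in results:
            rows.append({"direction": tag, **r.to_dict()})
        concordance[tag] = method_concordance(results)

    # measurement-error sensitivity: dichotomised education as exposure
    dich = TwoStageLeastSquares(
        df["mse"], df["edu_after_16"].astype(float), df["edu_score"],
        covariates=df[list(MODEL_A_COVARIATES)].to_numpy(float),
        exposure="edu_after_16", outcome="mse",
    ).fit(dwh=True)
    rows.append({"direction": "edu_to_mse_dichotomised", **dich.to_dict()})

    _round_trip(pd.DataFrame(rows), out / "sensitivity_twosample.tsv")
    (out / "concordance.json").write_text(json.dumps(concordance, indent=2))

    scan = confounder_scan(
        df, {"edu_score": df["edu_score"], "myo_score": df["myo_score"]},
        BIAS_COVARIATES, exposure="edu_years", outcome="mse",
    )
    _round_trip(scan, out / "confounder_scan.tsv")

    bias_rows = []
    for direction, score_col, expo, outc in (
        ("edu_to_mse", "edu_score", "edu_years", "mse"),
        ("mse_to_edu", "myo_score", "mse", "edu_years"),
    ):
        for cov in BIAS_COVARIATES:
            bc = bias_components(df, df[score_col], cov, expo, outc)
            bias_rows.append({"direction": direction, **bc.__dict__})
    _round_trip(pd.DataFrame(bias_rows), out / "bias_components.tsv")

    manifest.artifacts.update(
        {
            "summary_stats_fwd": str(out / "summary_stats_edu_to_mse.tsv"),
            "summary_stats_rev": str(out / "summary_stats_mse_to_edu.tsv"),
            "sensitivity": str(out / "sensitivity_twosample.tsv"),
            "concordance": str(out / "concordance.json"),
            "confounder_scan": str(out / "confounder_scan.tsv"),
            "bias_components": str(out / "bias_components.tsv"),
        }
    )


def _stage_report(cfg, out, state, manifest) -> None:
    df, strength = state["df"], state["strength"]
    table, slopes = report_observational_binned(df)
    _round_trip(table, out / "binned_observational.tsv")
    (out / "binned_slopes.json").write_text(json.dumps(slopes, indent=2, default=float))

    n = len(df)
    power_rows = []
    for direction, tag, sd_x, sd_y in (
        ("edu_to_mse", "education_score_on_edu_years", cfg.sd_edu, cfg.sd_mse),
        ("mse_to_edu", "myopia_score_on_mse", cfg.sd_mse, cfg.sd_edu),
    ):
        r2 = strength[tag]["partial_r2"]
        mde = min_detectable_effect(n, r2, 0.8, 0.05, sd_x, sd_y)
        for beta in np.linspace(0, 2.5 * mde, 26):
            power_rows.append(
                {
                    "direction": direction,
                    "r2_xz": r2,
                    "beta": beta,
                    "power": mr_power(PowerSpec(n, r2, beta, 0.05, sd_x, sd_y)),
                    "min_detectable_effect_80pct": mde,
                }
            )
    _round_trip(pd.DataFrame(power_rows), out / "power.tsv")
    manifest.artifacts.update(
        {
            "binned_observational": str(out / "binned_observational.tsv"),
            "binned_slopes": str(out / "binned_slopes.json"),
            "power": str(out / "power.tsv"),
        }
    )
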