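"""Synthetic cohort generator.

Generates genotypes in Hardy-Weinberg equilibrium, latent education and
refractive-error phenotypes linked by a configurable structural model
(causal effects in either or both directions, a shared latent confounder,
and horizontal pleiotropy), questionnaire records, raw per-eye
autorefraction readings, and per-variant GWAS summary statistics.

The structural model (centred form; EDU in years, MSE in dioptres)::

    EDU* = sum_i w_i (d_i - 2 p_i) + a_E (age-55) + c_E U + eps_E  [+ b_ME MSE*]
    MSE* = b_EM EDU* + sum_k w_k (d_k - 2 p_k) + sum_i delta_i (d_i - 2 p_i)
           + a_M (age-55) + c_M U + eps_M

with U ~ N(0,1).  Per-variant effects ``w`` are rescaled jointly so the
allele scores explain the configured variance fractions in expectation,
and the residual variances are solved so each trait's marginal variance
matches its configured SD.  ``delta`` is the horizontal-pleiotropy path
(instrument variants acting on the outcome directly).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import ScenarioConfig
from .harmonize import VariantPanel, synthetic_panel

__all__ = [
    "GenotypeMatrix",
    "simulate_genotypes",
    "simulate_cohort",
    "compute_gwas_summaries",
    "CohortData",
]

COUNTRIES = np.array(["England", "Scotland", "Wales", "other"])
EYE_CONDITION_FLAGS = ("cataract", "laser_surgery", "trauma_vision_loss", "corneal_graft")
PC_COLUMNS = tuple(f"pc{i}" for i in range(1, 11))
COVARIATE_COLUMNS = ("townsend", "birth_weight", "breastfed", "northing", "easting") + PC_COLUMNS


@dataclass
class GenotypeMatrix:
    """Per-participant genotype probability triples for a set of variants.

    ``probabilities`` has shape (n_participants, n_variants, 3) holding
    (P(AA), P(Aa), P(aa)) with ``a`` the effect allele; each triple sums
    to one.  Missing genotypes are all-NaN triples.
    """

    participant_ids: np.ndarray
    variant_ids: np.ndarray
    probabilities: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    eaf_true: np.ndarray | None = None  # generative allele frequencies

    def __post_init__(self) -> None:
        self.participant_ids = np.asarray(self.participant_ids)
        self.variant_ids = np.asarray(self.variant_ids)
        self.probabilities = np.asarray(self.probabilities, float)
        self.effect_allele = np.asarray(self.effect_allele)
        self.other_allele = np.asarray(self.other_allele)
        n, m, k = self.probabilities.shape
        if k != 3 or n != len(self.participant_ids) or m != len(self.variant_ids):
            raise ValueError("probability array shape inconsistent with ids")
        sums = self.probabilities.sum(axis=2)
        ok = np.isnan(sums) | (np.abs(sums - 1.0) < 1e-9)
        if not ok.all():
            raise ValueError("genotype probability triples must sum to 1")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.probabilities) < -1e-12:
                raise ValueError("genotype probabilities must be nonnegative")

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    @property
    def dosages(self) -> np.ndarray:
        """Expected effect-allele counts, shape (n, m); NaN where missing."""
        p = self.probabilities
        return 2.0 * p[:, :, 2] + p[:, :, 1]

    def subset(self, variant_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = {v: i for i, v in enumerate(self.variant_ids)}
        cols = [idx[v] for v in variant_ids]
        return GenotypeMatrix(
            self.participant_ids,
            np.asarray(variant_ids),
            self.probabilities[:, cols, :],
            self.effect_allele[cols],
            self.other_allele[cols],
            None if self.eaf_true is None else self.eaf_true[cols],
        )

    @staticmethod
    def concat(a: "GenotypeMatrix", b: "GenotypeMatrix") -> "GenotypeMatrix":
        if not np.array_equal(a.participant_ids, b.participant_ids):
            raise ValueError("participant ids differ")
        eaf = None
        if a.eaf_true is not None and b.eaf_true is not None:
            eaf = np.concatenate([a.eaf_true, b.eaf_true])
        return GenotypeMatrix(
            a.participant_ids,
            np.concatenate([a.variant_ids, b.variant_ids]),
            np.concatenate([a.probabilities, b.probabilities], axis=1),
            np.concatenate([a.effect_allele, b.effect_allele]),
            np.concatenate([a.other_allele, b.other_allele]),
            eaf,
        )

    # -- minimal VCF interchange (GT:GP, one ALT per record) -------------

    def to_vcf(self, path: str | Path) -> None:
        """Write a minimal VCF 4.2 file with GT and GP FORMAT fields.

        REF is the non-effect allele and ALT the effect allele, so the
        ALT dosage equals the effect-allele dosage.
        """
        lines = [
            "##fileformat=VCFv4.2",
            "##source=edumr-synthetic",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            '##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype probabilities">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, self.participant_ids)),
        ]
        gt_codes = np.array(["0/0", "0/1", "1/1", "./."])
        for j, rsid in enumerate(self.variant_ids):
            gp = self.probabilities[:, j, :]
            miss = np.isnan(gp[:, 0])
            calls = np.where(miss, 3, np.argmax(gp, axis=1))
            cells = [
                "./.:.,.,."
                if miss[i]
                else f"{gt_codes[calls[i]]}:{gp[i,0]:.4g},{gp[i,1]:.4g},{gp[i,2]:.4g}"
                for i in range(gp.shape[0])
            ]
            lines.append(
                f"1\t{j + 1}\t{rsid}\t{self.other_allele[j]}\t{self.effect_allele[j]}"
                f"\t.\tPASS\t.\tGT:GP\t" + "\t".join(cells)
            )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_vcf(cls, path: str | Path) -> "GenotypeMatrix":
        """Read the minimal VCF dialect written by :meth:`to_vcf`."""
        header = None
        rows, rsids, eff, oth = [], [], [], []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("##") or not line:
                    continue
                if line.startswith("#CHROM"):
                    header = line.split("\t")
                    continue
                parts = line.split("\t")
                rsids.append(parts[2])
                oth.append(parts[3])
                eff.append(parts[4])
                triples = []
                for cell in parts[9:]:
                    gp = cell.split(":")[1]
                    if gp.startswith("."):
                        triples.append((np.nan, np.nan, np.nan))
                    else:
                        triples.append(tuple(float(x) for x in gp.split(",")))
                rows.append(triples)
        if header is None:
            raise ValueError(f"no #CHROM header in {path}")
        samples = np.asarray(header[9:])
        probs = np.asarray(rows, float).transpose(1, 0, 2)
        # normalise away 4-significant-digit rounding in the text format
        sums = probs.sum(axis=2, keepdims=True)
        with np.errstate(invalid="ignore"):
            probs = probs / sums
        return cls(samples, np.asarray(rsids), probs, np.asarray(eff), np.asarray(oth))


def simulate_genotypes(
    n: int,
    panel: VariantPanel,
    maf_range: tuple[float, float] | None = None,
    rng: np.random.Generator | int | None = None,
    imputation_noise: float = 0.0,
    eaf: Sequence[float] | None = None,
) -> GenotypeMatrix:
    """Draw biallelic genotypes under Hardy-Weinberg proportions.

    Allele frequencies come from ``eaf`` if given, else are sampled
    uniformly from ``maf_range`` per variant.  Hard calls are degenerate
    probability triples; ``imputation_noise`` in [0, 1] mixes each triple
    toward the population genotype distribution, emulating imputation
    uncertainty.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(panel) == 0:
        raise ValueError("panel is empty")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    m = len(panel)
    if eaf is None:
        if maf_range is None:
            raise ValueError("either maf_range or eaf is required")
        lo, hi = maf_range
        freqs = rng.uniform(lo, hi, m)
    else:
        freqs = np.asarray(eaf, float)
        if len(freqs) != m:
            raise ValueError("eaf length must match panel")

    counts = rng.binomial(2, freqs[None, :], size=(n, m))
    probs = np.zeros((n, m, 3))
    for g in range(3):
        probs[:, :, g] = counts == g
    if imputation_noise > 0:
        pop = np.stack(
            [(1 - freqs) ** 2, 2 * freqs * (1 - freqs), freqs**2], axis=-1
        )
        probs = (1 - imputation_noise) * probs + imputation_noise * pop[None, :, :]
    ids = np.array([f"P{i:07d}" for i in range(n)])
    return GenotypeMatrix(
        ids,
        np.asarray(panel.rsids),
        probs,
        panel.df["effect_allele"].to_numpy(),
        panel.df["other_allele"].to_numpy(),
        freqs,
    )


def _rescale_weights(raw: np.ndarray, dosage_var: np.ndarray, target_var: float) -> np.ndarray:
    """Jointly rescale raw effect sizes so Var(sum w_i d_i) = target_var."""
    if target_var <= 0:
        return np.zeros_like(raw)
    current = float(np.sum(raw**2 * dosage_var))
    if current <= 0:
        raise ValueError("cannot rescale weights: zero score variance")
    return raw * np.sqrt(target_var / current)


@dataclass
class CohortData:
    """Bundle returned by :func:`simulate_cohort`."""

    genotypes: GenotypeMatrix
    questionnaire: pd.DataFrame
    ophthalmic: pd.DataFrame
    edu_panel: VariantPanel
    myo_panel: VariantPanel
    truth: dict


def simulate_cohort(cfg: ScenarioConfig) -> CohortData:
    """Generate a full synthetic cohort under the configured structural model.

    Returns genotypes for the education and myopia instrument panels, a
    questionnaire table (education, country, eye conditions, covariates),
    raw per-eye autorefraction records, the two instrument panels with
    their calibrated generative weights, and a ``truth`` dict recording
    every generative parameter and the latent phenotypes.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_participants

    edu_panel = synthetic_panel(cfg.n_edu_variants, "edu_ssgac", rng, rsid_start=86_100_001)
    myo_panel = synthetic_panel(cfg.n_myo_variants, "myopia_23andme", rng, rsid_start=86_000_001)

    lo, hi = cfg.maf_range
    eaf_e = rng.uniform(lo, hi, cfg.n_edu_variants)
    eaf_m = rng.uniform(lo, hi, cfg.n_myo_variants)
    gm_e = simulate_genotypes(n, edu_panel, rng=rng, eaf=eaf_e,
                              imputation_noise=cfg.imputation_noise)
    gm_m = simulate_genotypes(n, myo_panel, rng=rng, eaf=eaf_m,
                              imputation_noise=cfg.imputation_noise)
    genotypes = GenotypeMatrix.concat(gm_e, gm_m)

    v_e = 2 * eaf_e * (1 - eaf_e) * (1 - cfg.imputation_noise) ** 2
    v_m = 2 * eaf_m * (1 - eaf_m) * (1 - cfg.imputation_noise) ** 2

    w_e = _rescale_weights(edu_panel.weights, v_e,
                           cfg.variance_explained_edu_score * cfg.sd_edu**2)
    w_m = _rescale_weights(myo_panel.weights, v_m,
                           cfg.variance_explained_myo_score * cfg.sd_mse**2)
    edu_panel = edu_panel.with_weights(w_e)
    myo_panel = myo_panel.with_weights(w_m)

    # pleiotropy on the instrument variants of the active causal direction
    target = cfg.pleiotropy_target
    if target == "auto":
        target = (
            "myo_to_edu"
            if (cfg.beta_causal_mse_to_edu != 0 and cfg.beta_causal_edu_to_mse == 0)
            else "edu_to_mse"
        )
    n_pleio = cfg.n_edu_variants if target == "edu_to_mse" else cfg.n_myo_variants
    if cfg.pleiotropy_mode == "none":
        delta = np.zeros(n_pleio)
    elif cfg.pleiotropy_mode == "balanced":
        delta = rng.normal(0.0, cfg.pleiotropy_sd, n_pleio)
    else:  # directional: all effects share one sign
        delta = np.abs(rng.normal(0.0, cfg.pleiotropy_sd, n_pleio))

    # covariates and confounder
    age = rng.uniform(40, 70, n)
    sex = rng.integers(0, 2, n).astype(float)
    u = rng.standard_normal(n)

    d_e = gm_e.dosages - 2 * eaf_e  # centred dosages
    d_m = gm_m.dosages - 2 * eaf_m
    var_age = 30**2 / 12  # variance of Uniform(40, 70)

    # residual variances solved so marginal variances hit the configured SDs
    b_em = cfg.beta_causal_edu_to_mse
    b_me = cfg.beta_causal_mse_to_edu
    v_score_e = float(np.sum(w_e**2 * v_e))
    v_score_m = float(np.sum(w_m**2 * v_m))
    var_pleio = float(np.sum(delta**2 * (v_e if target == "edu_to_mse" else v_m)))

    sig2_e = (
        cfg.sd_edu**2
        - v_score_e
        - cfg.confounder_effect_edu**2
        - cfg.age_effect_edu**2 * var_age
        - cfg.sex_effect_edu**2 / 4
    )
    cov_pleio_we = float(np.sum(w_e * delta * v_e)) if target == "edu_to_mse" else 0.0
    sig2_m = (
        cfg.sd_mse**2
        - b_em**2 * cfg.sd_edu**2
        - v_score_m
        - var_pleio
        - cfg.confounder_effect_mse**2
        - cfg.age_effect_mse**2 * var_age
        - cfg.sex_effect_mse**2 / 4
        - 2 * b_em * (
            cfg.confounder_effect_edu * cfg.confounder_effect_mse
            + cov_pleio_we
            + cfg.age_effect_edu * cfg.age_effect_mse * var_age
        )
    )
    if sig2_e <= 0 or sig2_m <= 0:
        raise ValueError(
            "structural variance components exceed configured trait SDs "
            f"(residual variances {sig2_e:.3f}, {sig2_m:.3f})"
        )

    e0 = (
        d_e @ w_e
        + cfg.age_effect_edu * (age - 55)
        + cfg.sex_effect_edu * (sex - 0.5)
        + cfg.confounder_effect_edu * u
        + rng.normal(0, np.sqrt(sig2_e), n)
    )
    m0 = (
        d_m @ w_m
        + cfg.age_effect_mse * (age - 55)
        + cfg.sex_effect_mse * (sex - 0.5)
        + cfg.confounder_effect_mse * u
        + rng.normal(0, np.sqrt(sig2_m), n)
    )
    if target == "edu_to_mse":
        m0 = m0 + d_e @ delta
    else:
        e0 = e0 + d_m @ delta

    # The exposure the analysis sees is the CODED years-of-education
    # (degree -> 21, completion age floored at 15), so in the triangular
    # forward case the causal effect acts on the coded variable: the
    # continuous latent only generates the questionnaire response.
    if b_me == 0:
        edu_c = e0
        latent_edu = cfg.mean_edu + edu_c
        edu_years_true = _code_education(latent_edu)
        mse_c = b_em * (edu_years_true - cfg.mean_edu) + m0
        latent_mse = cfg.mean_mse + mse_c
    elif b_em == 0:
        mse_c = m0
        latent_mse = cfg.mean_mse + mse_c
        edu_c = b_me * mse_c + e0
        latent_edu = cfg.mean_edu + edu_c
        edu_years_true = _code_education(latent_edu)
    else:  # simultaneous system, solved in reduced form on the latents
        det = 1.0 - b_em * b_me
        if abs(det) < 1e-9:
            raise ValueError("simultaneous causal effects with |1 - b_em*b_me| ~ 0")
        edu_c = (e0 + b_me * m0) / det
        mse_c = (m0 + b_em * e0) / det
        latent_edu = cfg.mean_edu + edu_c
        latent_mse = cfg.mean_mse + mse_c
        edu_years_true = _code_education(latent_edu)

    questionnaire = _build_questionnaire(cfg, rng, genotypes.participant_ids,
                                         latent_edu, age, sex, u)
    ophthalmic = _build_ophthalmic(cfg, rng, genotypes.participant_ids, latent_mse)

    truth = {
        "config": cfg.model_dump(),
        "simultaneous": cfg.simultaneous,
        "beta_causal_edu_to_mse": b_em,
        "beta_causal_mse_to_edu": b_me,
        "pleiotropy_target": target,
        "pleiotropy_mean": float(delta.mean()) if len(delta) else 0.0,
        "pleiotropy_effects": delta,
        "weights_edu": w_e,
        "weights_myo": w_m,
        "eaf_edu": eaf_e,
        "eaf_myo": eaf_m,
        "sigma_edu": float(np.sqrt(sig2_e)),
        "sigma_mse": float(np.sqrt(sig2_m)),
        "var_score_edu": v_score_e,
        "var_score_myo": v_score_m,
        "latent_edu": latent_edu,
        "edu_years_true": edu_years_true,
        "latent_mse": latent_mse,
        "confounder": u,
    }
    return CohortData(genotypes, questionnaire, ophthalmic, edu_panel, myo_panel, truth)


def _code_education(latent_edu: np.ndarray) -> np.ndarray:
    """Years of education as the analysis codes them: degree holders
    (latent >= 20.5) are 21, completion ages are rounded and floored at 15."""
    has_degree = latent_edu >= 20.5
    age_completed = np.clip(np.round(latent_edu), 13, 20)
    return np.where(has_degree, 21.0, np.maximum(age_completed, 15.0))


def _build_questionnaire(cfg, rng, ids, latent_edu, age, sex, u) -> pd.DataFrame:
    n = len(ids)
    has_degree = latent_edu >= 20.5
    age_completed = np.clip(np.round(latent_edu), 13, 20)
    age_completed = np.where(has_degree, np.nan, age_completed)
    missing = rng.random(n) < cfg.missing_education_rate
    has_degree = np.where(missing, False, has_degree)
    age_completed = np.where(missing, np.nan, age_completed)

    r = cfg.born_outside_rate
    country = rng.choice(
        COUNTRIES, n, p=[0.75 * (1 - r), 0.15 * (1 - r), 0.10 * (1 - r), r]
    )
    load = cfg.northing_u_loading
    northing = load * u + np.sqrt(max(1 - load**2, 0.0)) * rng.standard_normal(n)

    df = pd.DataFrame(
        {
            "participant_id": ids,
            "has_degree": has_degree.astype(bool),
            "age_completed_fte": age_completed,
            "country_of_birth": country,
            "age": age,
            "sex": sex,
            "townsend": rng.standard_normal(n),
            "birth_weight": rng.normal(3.35, 0.55, n),
            "breastfed": (rng.random(n) < 0.7).astype(float),
            "northing": northing,
            "easting": rng.standard_normal(n),
        }
    )
    for c in PC_COLUMNS:
        df[c] = rng.standard_normal(n)
    for flag in EYE_CONDITION_FLAGS:
        df[flag] = rng.random(n) < cfg.eye_condition_rate / len(EYE_CONDITION_FLAGS)
    return df


def _build_ophthalmic(cfg, rng, ids, latent_mse) -> pd.DataFrame:
    """Noisy sphere/cylinder decompositions of the latent refractive error.

    Cylinder follows the minus-cylinder convention (values <= 0); each
    eye's true MSE is the participant's latent MSE plus a between-eye
    offset, and every repeat reading adds independent instrument noise.
    A configured fraction of readings is flagged unreliable.
    """
    n = len(ids)
    frames = []
    for eye in ("right", "left"):
        eye_mse = latent_mse + rng.normal(0, cfg.eye_offset_sd, n)
        cyl_true = -np.abs(rng.normal(0, 0.6, n))
        sph_true = eye_mse - 0.5 * cyl_true
        for _ in range(cfg.n_repeats):
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": ids,
                        "eye": eye,
                        "visit": 0,
                        "sphere": sph_true + rng.normal(0, cfg.measurement_sd, n),
                        "cylinder": np.minimum(
                            cyl_true + rng.normal(0, cfg.measurement_sd, n), 0.0
                        ),
                        "unreliable": rng.random(n) < cfg.unreliable_rate,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def compute_gwas_summaries(
    genotypes,
    phenotype,
    covariates=None,
) -> pd.DataFrame:
    """Per-variant linear-regression associations of a phenotype on dosage.

    ``genotypes`` may be a :class:`GenotypeMatrix` or an (n, m) dosage
    array.  Covariates are projected out of both phenotype and dosages
    (Frisch-Waugh), so the slope equals the covariate-adjusted multiple
    regression coefficient.  Variants with zero dosage variance are kept
    but flagged ``valid=False``.

    Returns a DataFrame with columns rsid, beta, se, n, eaf, valid.
    """
    if hasattr(genotypes, "dosages"):
        dos = genotypes.dosages
        rsids = np.asarray(genotypes.variant_ids)
    else:
        dos = np.asarray(genotypes, float)
        rsids = np.array([f"v{j}" for j in range(dos.shape[1])])
    y = np.asarray(phenotype, float)
    n = len(y)
    if dos.shape[0] != n:
        raise ValueError("phenotype length does not match participants")

    # mean-impute missing dosages so every variant keeps the full n
    col_mean = np.nanmean(dos, axis=0)
    dos = np.where(np.isnan(dos), col_mean[None, :], dos)
    eaf = dos.mean(axis=0) / 2.0

    if covariates is not None:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.column_stack([np.ones(n), C])
    else:
        X = np.ones((n, 1))
    k = X.shape[1]
    # residualise phenotype and dosages on the covariate block
    coef_y, *_ = np.linalg.lstsq(X, y, rcond=None)
    y_res = y - X @ coef_y
    coef_d, *_ = np.linalg.lstsq(X, dos, rcond=None)
    d_res = dos - X @ coef_d

    sxx = np.sum(d_res**2, axis=0)
    valid = sxx > 1e-12
    beta = np.full(len(rsids), np.nan)
    se = np.full(len(rsids), np.nan)
    sxy = d_res.T @ y_res
    beta[valid] = sxy[valid] / sxx[valid]
    dof = n - k - 1
    rss = np.sum(y_res**2) - beta[valid] ** 2 * sxx[valid]
    se[valid] = np.sqrt(np.maximum(rss, 0.0) / max(dof, 1) / sxx[valid])
    return pd.DataFrame(
        {"rsid": rsids, "beta": beta, "se": se, "n": n, "eaf": eaf, "valid": valid}
    )
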