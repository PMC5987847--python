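"""Phenotype derivation and exclusion rules.

Turns raw autorefraction records into a per-participant mean spherical
equivalent (MSE, dioptres; negative = myopic) and questionnaire answers
into years of full-time education, then applies the cohort exclusion
rules (pre-existing eye conditions, country of birth, missing data).
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "mean_spherical_equivalent",
    "aggregate_refraction",
    "derive_education_years",
    "dichotomise_education",
    "apply_exclusions",
]

GB_COUNTRIES = ("England", "Scotland", "Wales")
EYE_CONDITION_FLAGS = ("cataract", "laser_surgery", "trauma_vision_loss", "corneal_graft")

#: Fixed attribution order for exclusion counting (first match wins).
EXCLUSION_ORDER = (
    "eye_condition",
    "country",
    "missing_education",
    "missing_refraction",
    "missing_genotype",
)


def mean_spherical_equivalent(sphere, cylinder):
    """MSE = spherical power + 0.5 x cylindrical power (dioptres)."""
    return np.asarray(sphere, float) + 0.5 * np.asarray(cylinder, float)


def aggregate_refraction(records: pd.DataFrame) -> pd.Series:
    """Per-participant MSE from repeated per-eye autorefraction readings.

    Keeps the baseline visit only and drops unreliable-flagged readings;
    averages sphere and cylinder per eye across the remaining repeats,
    computes each eye's MSE from the averaged powers, then averages the
    available eyes (a single eye is used when the other has no valid
    reading).  Participants with no valid reading in either eye are
    absent from the result.
    """
    rec = records
    if "visit" in rec.columns:
        rec = rec[rec["visit"] == rec["visit"].min()]
    if "unreliable" in rec.columns:
        rec = rec[~rec["unreliable"].astype(bool)]
    if rec.empty:
        return pd.Series(dtype=float, name="mse")
    per_eye = rec.groupby(["participant_id", "eye"])[["sphere", "cylinder"]].mean()
    eye_mse = mean_spherical_equivalent(per_eye["sphere"], per_eye["cylinder"])
    per_eye = per_eye.assign(mse=eye_mse)
    out = per_eye.groupby("participant_id")["mse"].mean()
    out.name = "mse"
    return out


def derive_education_years(q) -> pd.Series:
    """Years of full-time education from questionnaire answers.

    Degree holders are coded as having left full-time education at age
    21 (the completion-age question is only asked of non-degree holders);
    reported ages below 15 are floored at 15; otherwise the reported age
    is used.  Missing when neither a degree nor an age is available.
    """
    has_degree = q["has_degree"].astype(bool).to_numpy()
    age = pd.to_numeric(q["age_completed_fte"], errors="coerce").to_numpy(float)
    years = np.where(has_degree, 21.0, np.where(age < 15, 15.0, age))
    return pd.Series(years, index=q.index, name="edu_years")


def dichotomise_education(edu_years) -> pd.Series:
    """True iff full-time education was completed after age 16.

    Missing input propagates as missing (pandas nullable boolean).
    """
    y = pd.Series(pd.to_numeric(pd.Series(edu_years), errors="coerce"))
    out = pd.Series(pd.array(y > 16, dtype="boolean"))
    out[y.isna()] = pd.NA
    out.name = "edu_after_16"
    return out


def apply_exclusions(
    questionnaire: pd.DataFrame,
    mse: pd.Series,
    genotyped_ids: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Derive analysis phenotypes and apply the exclusion rules.

    A participant is excluded if any pre-existing eye-condition flag is
    set, if born outside England/Scotland/Wales, or if education,
    refraction or genotype data are missing.  Reasons are attributed
    first-match in :data:`EXCLUSION_ORDER`, so the per-reason counts sum
    exactly to the number of excluded rows.

    Returns the derived phenotype table (one row per questionnaire row,
    with ``included`` and ``exclusion_reason`` columns) and the counts by
    reason.
    """
    q = questionnaire.reset_index(drop=True)
    edu_years = derive_education_years(q)
    mse_map = q["participant_id"].map(mse)

    flags_present = [c for c in EYE_CONDITION_FLAGS if c in q.columns]
    eye_condition = (
        q[flags_present].astype(bool).any(axis=1)
        if flags_present
        else pd.Series(False, index=q.index)
    )
    bad_country = ~q["country_of_birth"].isin(GB_COUNTRIES)
    missing_edu = edu_years.isna()
    missing_mse = mse_map.isna()
    if genotyped_ids is not None:
        missing_geno = ~q["participant_id"].isin(set(genotyped_ids))
    else:
        missing_geno = pd.Series(False, index=q.index)

    reason = pd.Series(pd.NA, index=q.index, dtype="object")
    masks = {
        "eye_condition": eye_condition,
        "country": bad_country,
        "missing_education": missing_edu,
        "missing_refraction": missing_mse,
        "missing_genotype": missing_geno,
    }
    for name in EXCLUSION_ORDER:
        reason[masks[name] & reason.isna()] = name

    derived = pd.DataFrame(
        {
            "participant_id": q["participant_id"],
            "edu_years": edu_years,
            "edu_after_16": dichotomise_education(edu_years),
            "mse": mse_map,
            "included": reason.isna(),
            "exclusion_reason": reason,
        }
    )
    counts = {name: int((reason == name).sum()) for name in EXCLUSION_ORDER}
    counts["included"] = int(derived["included"].sum())
    counts["total"] = len(q)
    return derived, counts
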