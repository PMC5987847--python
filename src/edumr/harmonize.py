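"""Instrument panels, allele harmonisation, dosages and allele scores.

A :class:`VariantPanel` holds per-variant instrument definitions (rsID,
effect allele, other allele, per-allele weight from the discovery GWAS).
Panels are filtered against an imputation reference, oriented to the
cohort's counted allele, and combined with genotype dosages into a single
weighted allele score per participant::

    S_j = sum_i  w_i * d_ij

where ``d_ij`` in [0, 2] is the expected count of the effect allele.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "MYOPIA_VARIANTS_NOT_IN_HRC",
    "EDUCATION_VARIANTS_NOT_IN_HRC",
    "VariantPanel",
    "AlleleScore",
    "Orientation",
    "filter_to_reference",
    "probabilities_to_dosage",
    "harmonize_effect_allele",
    "build_allele_score",
    "score_strength",
    "f_from_partial_r2",
    "synthetic_panel",
    "demo_myopia_panel",
    "demo_education_panel",
    "hrc_reference_ids",
]

# Myopia GWAS hits absent from the Haplotype Reference Consortium panel;
# excluding them from the 50 reported variants leaves the 44 instruments.
MYOPIA_VARIANTS_NOT_IN_HRC = (
    "rs5022942",
    "rs10887265",
    "rs71041628",
    "rs34016308",
    "rs11658305",
    "rs201140091",
)

# Education GWAS hits absent from the HRC panel; excluding them from the
# 74 reported variants leaves the 69 instruments.
EDUCATION_VARIANTS_NOT_IN_HRC = (
    "rs9320913",
    "rs148734725",
    "rs544990728",
    "rs114598875",
    "rs8005528",
)

_PANEL_COLUMNS = ["rsid", "effect_allele", "other_allele", "weight", "eaf", "source"]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMES = ({"A", "T"}, {"C", "G"})


@dataclass
class VariantPanel:
    """Table of instrument variants with effect alleles and weights."""

    df: pd.DataFrame
    panel_id: str = "panel"

    def __post_init__(self) -> None:
        df = self.df.copy()
        if "eaf" not in df.columns:
            df["eaf"] = np.nan
        if "source" not in df.columns:
            df["source"] = self.panel_id
        missing = [c for c in _PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"panel missing columns: {missing}")
        df = df[_PANEL_COLUMNS].reset_index(drop=True)
        if df["rsid"].duplicated().any():
            dups = df.loc[df["rsid"].duplicated(), "rsid"].tolist()
            raise ValueError(f"duplicate rsids in panel: {dups}")
        if (df["effect_allele"] == df["other_allele"]).any():
            raise ValueError("effect and other allele must differ")
        if not np.isfinite(df["weight"].to_numpy(float)).all():
            raise ValueError("weights must be finite")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def rsids(self) -> list[str]:
        return self.df["rsid"].tolist()

    @property
    def weights(self) -> np.ndarray:
        return self.df["weight"].to_numpy(float)

    def with_weights(self, weights: Sequence[float]) -> "VariantPanel":
        df = self.df.copy()
        df["weight"] = np.asarray(weights, float)
        return VariantPanel(df, panel_id=self.panel_id)

    # -- tab-separated text I/O ------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path, panel_id: str | None = None) -> "VariantPanel":
        df = pd.read_csv(path, sep="\t")
        return cls(df, panel_id=panel_id or Path(path).stem)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


@dataclass
class AlleleScore:
    """Weighted allele score per participant, in trait-prediction units."""

    participant_ids: np.ndarray
    values: np.ndarray
    panel_id: str = "score"

    def __post_init__(self) -> None:
        self.participant_ids = np.asarray(self.participant_ids)
        self.values = np.asarray(self.values, float)
        if len(self.participant_ids) != len(self.values):
            raise ValueError("participant_ids and values length mismatch")
        if not np.isfinite(self.values).all():
            raise ValueError("allele score contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def series(self) -> pd.Series:
        return pd.Series(self.values, index=self.participant_ids, name=self.panel_id)


class Orientation(str, enum.Enum):
    SAME = "same"
    FLIP = "flip"
    DROP = "drop"


def filter_to_reference(
    panel: VariantPanel, reference_ids: Iterable[str]
) -> tuple[VariantPanel, list[str]]:
    """Restrict a panel to variants present in an imputation reference.

    Returns the retained panel and the ordered list of excluded rsIDs.
    Raises ``ValueError`` if nothing survives (no instruments left).
    """
    ref = set(reference_ids)
    keep_mask = panel.df["rsid"].isin(ref)
    excluded = panel.df.loc[~keep_mask, "rsid"].tolist()
    kept = panel.df.loc[keep_mask]
    if kept.empty:
        raise ValueError(
            f"no instruments remain after reference filtering of {panel.panel_id}"
        )
    return VariantPanel(kept, panel_id=panel.panel_id), excluded


def probabilities_to_dosage(triple, tol: float = 1e-6):
    """Convert genotype probabilities (P_AA, P_Aa, P_aa) to effect-allele
    dosage ``2*P_aa + P_Aa`` in [0, 2].

    Accepts a single triple or an array whose last axis has length 3.
    """
    arr = np.asarray(triple, float)
    if arr.shape[-1] != 3:
        raise ValueError("genotype probabilities must have last dimension 3")
    if np.nanmin(arr) < -tol:
        raise ValueError("negative genotype probabilities")
    sums = arr.sum(axis=-1)
    finite = np.isfinite(sums)
    if np.any(np.abs(sums[finite] - 1.0) > tol):
        raise ValueError("genotype probability triples must sum to 1")
    dosage = 2.0 * arr[..., 2] + arr[..., 1]
    return float(dosage) if dosage.ndim == 0 else dosage


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in _PALINDROMES


def harmonize_effect_allele(
    effect_allele: str,
    other_allele: str,
    cohort_counted: str,
    cohort_other: str,
    cohort_eaf: float | None = None,
    palindrome_maf_window: tuple[float, float] = (0.42, 0.5),
) -> tuple[Orientation, str | None]:
    """Decide how a panel variant maps onto the cohort's counted allele.

    Returns ``(orientation, reason)``. ``SAME`` keeps the dosage, ``FLIP``
    replaces it by ``2 - d``, and ``DROP`` removes the variant (strand
    ambiguous palindromic variant near 50% frequency, or inconsistent
    allele sets).  Strand flips are resolved through base complements.
    """
    ea, oa = effect_allele.upper(), other_allele.upper()
    c1, c2 = cohort_counted.upper(), cohort_other.upper()

    if _is_palindromic(ea, oa):
        maf_lo, maf_hi = palindrome_maf_window
        if cohort_eaf is None:
            return Orientation.DROP, "palindromic variant with unknown frequency"
        maf = min(cohort_eaf, 1.0 - cohort_eaf)
        if maf_lo <= maf <= maf_hi:
            return Orientation.DROP, (
                f"palindromic variant with ambiguous frequency (MAF={maf:.3f})"
            )

    if {ea, oa} == {c1, c2}:
        return (Orientation.SAME, None) if ea == c1 else (Orientation.FLIP, None)

    comp = {_COMPLEMENT[a] for a in (ea, oa) if a in _COMPLEMENT}
    if comp == {c1, c2}:
        return (
            (Orientation.SAME, None)
            if _COMPLEMENT.get(ea) == c1
            else (Orientation.FLIP, None)
        )
    return Orientation.DROP, f"allele sets inconsistent ({ea}/{oa} vs {c1}/{c2})"


def build_allele_score(genotypes, panel: VariantPanel) -> AlleleScore:
    """Weighted sum of harmonised effect-allele dosages, no standardisation.

    Every panel variant must be present in ``genotypes`` (a
    :class:`~edumr.simulate.GenotypeMatrix`); missing variants raise with
    the offending rsIDs.  Dosages are flipped to ``2 - d`` where the
    cohort counts the panel's other allele.  Missing per-participant
    dosages are imputed with twice the cohort effect-allele frequency.
    """
    idx = {v: i for i, v in enumerate(np.asarray(genotypes.variant_ids))}
    missing = [r for r in panel.rsids if r not in idx]
    if missing:
        raise ValueError(f"variants missing from genotypes: {missing}")

    dosages = genotypes.dosages
    n = dosages.shape[0]
    score = np.zeros(n)
    for _, row in panel.df.iterrows():
        j = idx[row["rsid"]]
        d = dosages[:, j].astype(float).copy()
        eaf = np.nanmean(d) / 2.0
        d[np.isnan(d)] = 2.0 * eaf  # mean imputation keeps n constant
        orient, reason = harmonize_effect_allele(
            row["effect_allele"],
            row["other_allele"],
            genotypes.effect_allele[j],
            genotypes.other_allele[j],
            cohort_eaf=eaf,
        )
        if orient is Orientation.DROP:
            raise ValueError(f"variant {row['rsid']} cannot be harmonised: {reason}")
        if orient is Orientation.FLIP:
            d = 2.0 - d
        score += row["weight"] * d
    return AlleleScore(np.asarray(genotypes.participant_ids), score, panel.panel_id)


def score_strength(score, phenotype, covariates=None) -> tuple[float, float]:
    """Instrument strength of an allele score: partial R^2 and first-stage F.

    ``partial_R2`` is the incremental R^2 of adding the score to the
    covariate-only regression of the phenotype, and

        F = partial_R2 / (1 - partial_R2) * (n - p - 1)

    with ``p`` the number of (non-constant) regressors in the full
    first-stage model.  A perfect fit returns ``F = inf``.
    """
    s = np.asarray(getattr(score, "values", score), float)
    y = np.asarray(phenotype, float)
    if s.std() == 0 or y.std() == 0:
        raise ValueError("constant score or phenotype")
    n = len(y)
    if covariates is not None:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
    else:
        C = np.empty((n, 0))
    p = C.shape[1] + 1
    if n <= p + 1:
        raise ValueError("too few observations for first-stage regression")

    full = sm.OLS(y, sm.add_constant(np.column_stack([s, C]))).fit()
    if C.shape[1]:
        base = sm.OLS(y, sm.add_constant(C)).fit()
        r2_base = base.rsquared
    else:
        r2_base = 0.0
    partial_r2 = (full.rsquared - r2_base) / (1.0 - r2_base)
    partial_r2 = float(min(max(partial_r2, 0.0), 1.0))
    if partial_r2 >= 1.0 - 1e-12:
        return 1.0, float("inf")
    f_stat = f_from_partial_r2(partial_r2, n, C.shape[1])
    return partial_r2, float(f_stat)


def f_from_partial_r2(partial_r2: float, n: int, n_covariates: int = 0) -> float:
    """First-stage F from a partial R^2 and sample size:
    ``F = R2/(1-R2) * (n - p - 1)`` with ``p`` counting the score plus
    covariates in the first-stage model."""
    if not (0 <= partial_r2 < 1):
        raise ValueError("partial_r2 must lie in [0, 1)")
    p = n_covariates + 1
    return float(partial_r2 / (1.0 - partial_r2) * (n - p - 1))


# -- synthetic panel construction ----------------------------------------

_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("G", "A"), ("C", "A"),
    ("T", "G"), ("T", "C"), ("G", "T"), ("C", "T"),
]


def synthetic_panel(
    n_variants: int,
    source: str,
    rng: np.random.Generator | int | None = None,
    rsid_start: int = 86_000_001,
    weight_sd: float = 0.05,
) -> VariantPanel:
    """Generate a synthetic instrument panel with non-palindromic alleles.

    rsIDs are drawn from a reserved synthetic range so they cannot collide
    with the real GWAS identifiers used in reference-filtering examples.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), n_variants)]
    df = pd.DataFrame(
        {
            "rsid": [f"rs{rsid_start + i}" for i in range(n_variants)],
            "effect_allele": [p[0] for p in pairs],
            "other_allele": [p[1] for p in pairs],
            "weight": rng.normal(0.0, weight_sd, n_variants),
            "eaf": np.nan,
            "source": source,
        }
    )
    return VariantPanel(df, panel_id=source)


def demo_myopia_panel(rng: np.random.Generator | int | None = None) -> VariantPanel:
    """The 50-variant myopia discovery panel: 44 synthetic stand-ins plus
    the six real rsIDs known to be absent from the HRC reference."""
    base = synthetic_panel(44, "myopia_23andme", rng, rsid_start=86_000_001)
    extra = pd.DataFrame(
        {
            "rsid": MYOPIA_VARIANTS_NOT_IN_HRC,
            "effect_allele": "A",
            "other_allele": "G",
            "weight": 0.05,
            "eaf": np.nan,
            "source": "myopia_23andme",
        }
    )
    return VariantPanel(pd.concat([base.df, extra], ignore_index=True), "myopia_23andme")


def demo_education_panel(rng: np.random.Generator | int | None = None) -> VariantPanel:
    """The 74-variant education discovery panel: 69 synthetic stand-ins
    plus the five real rsIDs known to be absent from the HRC reference."""
    base = synthetic_panel(69, "edu_ssgac", rng, rsid_start=86_100_001)
    extra = pd.DataFrame(
        {
            "rsid": EDUCATION_VARIANTS_NOT_IN_HRC,
            "effect_allele": "A",
            "other_allele": "G",
            "weight": 0.02,
            "eaf": np.nan,
            "source": "edu_ssgac",
        }
    )
    return VariantPanel(pd.concat([base.df, extra], ignore_index=True), "edu_ssgac")


def hrc_reference_ids(*panels: VariantPanel) -> set[str]:
    """Synthetic stand-in for HRC membership: every panel rsID except the
    identifiers documented as absent from the reference."""
    absent = set(MYOPIA_VARIANTS_NOT_IN_HRC) | set(EDUCATION_VARIANTS_NOT_IN_HRC)
    ids: set[str] = set()
    for p in panels:
        ids.update(p.rsids)
    return ids - absent
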