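"""Scenario configuration for the synthetic cohort generator.

A :class:`ScenarioConfig` fully determines one synthetic cohort: the
instrument panels, the structural model linking years of education and
refractive error, confounding, pleiotropy, and the raw-measurement layer.
All randomness flows from the single ``seed``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Tuple

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = ["ScenarioConfig"]


class ScenarioConfig(BaseModel):
    """Generative parameters for a synthetic education/myopia cohort.

    The defaults describe the forward-causal scenario: one extra year of
    education shifts refractive error by ``beta_causal_edu_to_mse``
    dioptres, the education allele score explains 0.71% of the variance in
    years of education and the myopia allele score 4.32% of the variance
    in mean spherical equivalent (MSE), and a latent confounder acts on
    both traits.

    Units: education in years, refractive error in dioptres (negative =
    myopic), confounder effects per SD of the latent confounder,
    per-variant pleiotropic effects in dioptres per effect allele.
    """

    n_participants: int = Field(default=20_000, ge=1)
    n_edu_variants: int = Field(default=69, ge=1)
    n_myo_variants: int = Field(default=44, ge=1)
    maf_range: Tuple[float, float] = (0.05, 0.5)

    beta_causal_edu_to_mse: float = -0.27  # dioptres per year
    beta_causal_mse_to_edu: float = 0.0  # years per dioptre

    # Calibrated so the covariate-adjusted observational slope of MSE on
    # the coded education variable attenuates to ~-0.18 D/y while the
    # causal effect is -0.27 D/y (the scenario's headline contrast).
    confounder_effect_edu: float = 1.0  # years per confounder-SD
    confounder_effect_mse: float = 0.51  # dioptres per confounder-SD

    pleiotropy_mode: Literal["none", "balanced", "directional"] = "none"
    pleiotropy_sd: float = Field(default=0.02, ge=0.0)  # dioptres per allele
    pleiotropy_target: Literal["auto", "edu_to_mse", "myo_to_edu"] = "auto"

    variance_explained_edu_score: float = 0.0071
    variance_explained_myo_score: float = 0.0432

    # Marginal trait scales; biobank-scale SDs are not published so these
    # are config-exposed conventions (see docs/methods.md).
    sd_edu: float = Field(default=2.5, gt=0)
    sd_mse: float = Field(default=2.7, gt=0)
    mean_edu: float = 17.3
    mean_mse: float = -0.3

    # Covariate effects (exogenous; adjusted for in all analyses).
    age_effect_edu: float = -0.02  # years of education per year of age
    age_effect_mse: float = 0.004  # dioptres per year of age
    sex_effect_edu: float = 0.0
    sex_effect_mse: float = 0.0
    # Loading of the synthetic northing coordinate on the confounder,
    # emulating a geographic covariate that tracks the confounding path.
    northing_u_loading: float = Field(default=0.2, ge=-1.0, le=1.0)

    # Raw ophthalmic measurement layer.
    n_repeats: int = Field(default=2, ge=1, le=10)
    measurement_sd: float = Field(default=0.25, ge=0)  # dioptres per reading
    eye_offset_sd: float = Field(default=0.15, ge=0)  # between-eye spread
    unreliable_rate: float = Field(default=0.05, ge=0, le=1)

    # Questionnaire / exclusion layer.
    eye_condition_rate: float = Field(default=0.08, ge=0, le=1)
    born_outside_rate: float = Field(default=0.05, ge=0, le=1)
    missing_education_rate: float = Field(default=0.02, ge=0, le=1)

    imputation_noise: float = Field(default=0.0, ge=0, le=1)

    seed: int = 0

    @field_validator("maf_range")
    @classmethod
    def _check_maf_range(cls, v: Tuple[float, float]) -> Tuple[float, float]:
        lo, hi = v
        if not (0 <= lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 <= lo <= hi <= 0.5")
        return (float(lo), float(hi))

    @field_validator("variance_explained_edu_score", "variance_explained_myo_score")
    @classmethod
    def _check_r2(cls, v: float) -> float:
        if not (0 <= v < 1):
            raise ValueError("variance fractions must lie in [0, 1)")
        return v

    @model_validator(mode="after")
    def _check_variance_budget(self) -> "ScenarioConfig":
        # The score, confounder and covariate components must leave room
        # for residual noise at the configured marginal SDs.
        v_edu = self.sd_edu**2
        used = (
            self.variance_explained_edu_score * v_edu
            + self.confounder_effect_edu**2
            + self.age_effect_edu**2 * (30**2 / 12)
            + self.sex_effect_edu**2 / 4
        )
        if used >= v_edu:
            raise ValueError(
                "education variance components exceed sd_edu^2; reduce "
                "confounder/covariate effects or raise sd_edu"
            )
        return self

    @property
    def simultaneous(self) -> bool:
        """True when both causal directions are active at once."""
        return (
            self.beta_causal_edu_to_mse != 0 and self.beta_causal_mse_to_edu != 0
        )

    # -- file I/O ---------------------------------------------------------

    @classmethod
    def from_file(cls, path: str | Path) -> "ScenarioConfig":
        """Load a config from YAML or JSON (YAML is a JSON superset)."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        p = Path(path)
        data = self.model_dump()
        data["maf_range"] = list(data["maf_range"])
        if p.suffix == ".json":
            p.write_text(json.dumps(data, indent=2))
        else:
            p.write_text(yaml.safe_dump(data, sort_keys=False))

    def config_hash(self) -> str:
        import hashlib

        blob = json.dumps(self.model_dump(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
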