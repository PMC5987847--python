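"""Shared results container for all Mendelian-randomisation estimators."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["MRResult"]


@dataclass
class MRResult:
    """A causal-effect estimate with uncertainty and diagnostics.

    ``estimate`` is in outcome units per exposure unit.  ``ci95`` is the
    normal-approximation interval ``estimate +/- 1.96 * se``.  For
    Egger-type fits ``intercept`` carries the directional-pleiotropy
    intercept as a dict with keys estimate/se/p.
    """

    method: str
    exposure: str
    outcome: str
    estimate: float
    se: float
    p: float
    n: int
    ci95: tuple[float, float] = None  # type: ignore[assignment]
    first_stage_F: Optional[float] = None
    partial_r2: Optional[float] = None
    intercept: Optional[dict] = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ci95 is None:
            self.ci95 = (self.estimate - 1.96 * self.se, self.estimate + 1.96 * self.se)
        self.ci95 = (float(self.ci95[0]), float(self.ci95[1]))
        if not (np.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError("p-value outside [0, 1]")

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "exposure": self.exposure,
            "outcome": self.outcome,
            "estimate": self.estimate,
            "se": self.se,
            "ci95_low": self.ci95[0],
            "ci95_high": self.ci95[1],
            "p": self.p,
            "n": self.n,
            "first_stage_F": self.first_stage_F,
            "partial_r2": self.partial_r2,
        }
        if self.intercept is not None:
            d["intercept"] = self.intercept["estimate"]
            d["intercept_se"] = self.intercept["se"]
            d["intercept_p"] = self.intercept["p"]
        d.update({f"diag_{k}": v for k, v in self.diagnostics.items()})
        return d

    def summary(self) -> str:
        lines = [
            f"{self.method} estimate: {self.exposure} -> {self.outcome}",
            "-" * 56,
            f"{'estimate':<22}{self.estimate: .4f}",
            f"{'std err':<22}{self.se: .4f}",
            f"{'95% CI':<22}[{self.ci95[0]: .4f}, {self.ci95[1]: .4f}]",
            f"{'p-value':<22}{self.p: .3g}",
            f"{'n':<22}{self.n}",
        ]
        if self.first_stage_F is not None:
            lines.append(f"{'first-stage F':<22}{self.first_stage_F: .1f}")
        if self.partial_r2 is not None:
            lines.append(f"{'partial R2':<22}{self.partial_r2: .4f}")
        if self.intercept is not None:
            lines.append(
                f"{'intercept (pleiotropy)':<22}{self.intercept['estimate']: .4f}"
                f" (SE {self.intercept['se']:.4f}, p {self.intercept['p']:.3g})"
            )
        for k, v in self.diagnostics.items():
            lines.append(f"{k:<22}{v}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # terse, informative in notebooks
        return (
            f"MRResult({self.method}, {self.exposure}->{self.outcome}, "
            f"b={self.estimate:.4g}, se={self.se:.3g}, p={self.p:.3g}, n={self.n})"
        )
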