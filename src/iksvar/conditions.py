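"""cRNA injection conditions for oocyte expression experiments.

Condition labels encode the injected construct mix: wild-type KCNQ1 at full
or half dose, heterozygous WT+variant mixes, homomeric variant, each with or
without the KCNE1 beta-subunit, plus the two background controls (KCNE1
alone, which recruits endogenous Xenopus KCNQ1 into xIKs, and non-injected
oocytes).  Doses follow the published injection scheme: 14.5 / 7.25 ng
KCNQ1 cRNA per oocyte without KCNE1, 81.2 / 40.6 ng with 1 ng KCNE1.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

__all__ = ["ConditionLabel", "Condition", "standard_condition", "STANDARD_DOSES_NG"]


class ConditionLabel(str, Enum):
    WT100 = "WT100"
    WT50 = "WT50"
    HET = "HET"
    VAR100 = "VAR100"
    WT100_E1 = "WT100_E1"
    WT50_E1 = "WT50_E1"
    HET_E1 = "HET_E1"
    VAR100_E1 = "VAR100_E1"
    E1_ONLY = "E1_ONLY"
    NONINJ = "NONINJ"

    @property
    def with_kcne1(self) -> bool:
        return self in (
            ConditionLabel.WT100_E1,
            ConditionLabel.WT50_E1,
            ConditionLabel.HET_E1,
            ConditionLabel.VAR100_E1,
            ConditionLabel.E1_ONLY,
        )

    @property
    def has_variant(self) -> bool:
        return self in (
            ConditionLabel.HET,
            ConditionLabel.VAR100,
            ConditionLabel.HET_E1,
            ConditionLabel.VAR100_E1,
        )


# (kcnq1_wt_ng, kcnq1_var_ng, kcne1_ng) per oocyte
STANDARD_DOSES_NG: dict[ConditionLabel, tuple[float, float, float]] = {
    ConditionLabel.WT100: (14.5, 0.0, 0.0),
    ConditionLabel.WT50: (7.25, 0.0, 0.0),
    ConditionLabel.HET: (7.25, 7.25, 0.0),
    ConditionLabel.VAR100: (0.0, 14.5, 0.0),
    ConditionLabel.WT100_E1: (81.2, 0.0, 1.0),
    ConditionLabel.WT50_E1: (40.6, 0.0, 1.0),
    ConditionLabel.HET_E1: (40.6, 40.6, 1.0),
    ConditionLabel.VAR100_E1: (0.0, 81.2, 1.0),
    ConditionLabel.E1_ONLY: (0.0, 0.0, 1.0),
    ConditionLabel.NONINJ: (0.0, 0.0, 0.0),
}


@dataclass(frozen=True)
class Condition:
    """One injection condition, with cRNA doses in ng/oocyte."""

    label: ConditionLabel
    kcnq1_wt_ng: float
    kcnq1_var_ng: float
    kcne1_ng: float
    variant_id: str = ""

    def __post_init__(self) -> None:
        for name in ("kcnq1_wt_ng", "kcnq1_var_ng", "kcne1_ng"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.label in (ConditionLabel.HET, ConditionLabel.HET_E1):
            if self.kcnq1_wt_ng != self.kcnq1_var_ng:
                raise ValueError("heterozygous conditions use equal WT and variant doses")
        if self.label.has_variant and not self.variant_id:
            raise ValueError(f"{self.label.value} requires a variant_id")
        if not self.label.has_variant and self.variant_id:
            raise ValueError(f"{self.label.value} must not carry a variant_id")


def standard_condition(label: ConditionLabel | str, variant_id: str = "") -> Condition:
    """Condition with the standard published doses for ``label``."""
    label = ConditionLabel(label)
    wt, var, e1 = STANDARD_DOSES_NG[label]
    return Condition(label, wt, var, e1, variant_id if label.has_variant else "")
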