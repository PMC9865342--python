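"""Bundled fixture tables: per-variant effect sizes and patient QTc values.

``variant_effects_paper.json`` holds, for each of the nine KCNQ1 variants
and each expression context (with/without KCNE1, homo-/heterozygous), the
relative current amplitude r and the activation shift dV1/2.  Entries are
tagged by provenance: ``"text"`` for the four effect sizes documented
numerically for these variants (G119R het+KCNE1 r=0.74, K421E het+KCNE1
r=0.84 and homo+KCNE1 r=0.34, R591C het+KCNE1 r=0.72);
``"figure_placeholder"`` for approximate values read off figures, bundled
so every pipeline stage is runnable for every variant.

``patients_qtc.csv`` lists the Bazett-corrected QTc intervals documented
for variant-carrying index patients and relatives.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from importlib import resources

from .analysis import VariantEffect

__all__ = [
    "load_variant_effects",
    "variant_effect",
    "variant_ids",
    "PatientQtc",
    "load_patients_qtc",
]

_cache: dict | None = None


def _raw() -> dict:
    global _cache
    if _cache is None:
        with resources.files("iksvar.data").joinpath("variant_effects_paper.json").open() as fh:
            _cache = json.load(fh)
    return _cache


def variant_ids() -> list[str]:
    """The nine characterized KCNQ1 variants."""
    return list(_raw()["variants"])


def load_variant_effects(sources: tuple[str, ...] = ("text", "figure_placeholder")) -> list[VariantEffect]:
    """All fixture entries as :class:`VariantEffect` records."""
    raw = _raw()
    default_v = raw["default_analysis_voltage_mV"]
    out = []
    for vid, block in raw["variants"].items():
        for e in block["entries"]:
            if e["source"] not in sources:
                continue
            r = e["r"]
            out.append(
                VariantEffect(
                    variant_id=vid,
                    context=e["context"],
                    zygosity=e["zygosity"],
                    r=r,
                    percent_change=100.0 * (1.0 - r),
                    delta_v_half_mV=e["delta_v_half_mV"],
                    analysis_voltage_mV=e.get("analysis_voltage_mV", default_v),
                    source=e["source"],
                )
            )
    return out


def variant_effect(variant_id: str, context: str = "WITH_E1", zygosity: str = "HET") -> VariantEffect:
    """One fixture entry; raises ``KeyError`` for unknown combinations."""
    for eff in load_variant_effects():
        if (eff.variant_id, eff.context, eff.zygosity) == (variant_id, context, zygosity):
            return eff
    raise KeyError(f"no fixture entry for {variant_id} / {context} / {zygosity}")


@dataclass(frozen=True)
class PatientQtc:
    variant: str
    subject: str
    sex: str  # MALE | FEMALE | UNKNOWN
    qtc_ms: float | None
    note: str


def load_patients_qtc() -> list[PatientQtc]:
    """Documented patient QTc values per variant."""
    with resources.files("iksvar.data").joinpath("patients_qtc.csv").open() as fh:
        rows = list(csv.DictReader(fh))
    return [
        PatientQtc(
            variant=r["variant"],
            subject=r["subject"],
            sex=r["sex"],
            qtc_ms=float(r["qtc_ms"]) if r["qtc_ms"] else None,
            note=r["note"],
        )
        for r in rows
    ]
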