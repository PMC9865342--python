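"""End-to-end study workflows built from the pipeline stages.

These functions run the headline end-to-end computations from scratch:
synthetic-data generation at the default recording-campaign conditions (3 days,
10 oocytes per condition per day, default variability), the day-normalized
amplitude analysis, and the G119R cell/tissue simulations.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .analysis import (
    classify_variant,
    measure,
    normalize_by_day,
    percent_reduction,
    relative_amplitude_se,
)
from .cell_model import CellModelParams, CellType, Series, apd_change, apply_effect, pace_to_limit_cycle
from .conditions import ConditionLabel, standard_condition
from .fixtures import variant_effect
from .generator import GeneratorConfig, generate_dataset
from .protocols import make_protocol
from .pseudo_ecg import CableSpec, measure_qt, pseudo_ecg, qt_percent_change, run_cable

__all__ = [
    "recover_percent_reduction",
    "noninjected_mean_nA",
    "apd90_percent_change",
    "ecg_qt_percent_change",
]


def recover_percent_reduction(
    variant_id: str,
    zygosity: str,
    seed: int,
    config: GeneratorConfig | None = None,
) -> tuple[float, float, int]:
    """Generate clamp data with the fixture truth and re-estimate the
    percent current reduction at +40 mV.

    Returns (percent reduction, its standard error in percent, n oocytes in
    the variant group).
    """
    eff = variant_effect(variant_id, "WITH_E1", zygosity)
    label = ConditionLabel.HET_E1 if zygosity == "HET" else ConditionLabel.VAR100_E1
    cfg = (config or GeneratorConfig()).with_truth(
        label, variant_id, eff.r, eff.delta_v_half_mV or 0.0
    )
    conditions = [
        standard_condition(ConditionLabel.WT100_E1),
        standard_condition(label, variant_id),
        standard_condition(ConditionLabel.E1_ONLY),
    ]
    dataset = generate_dataset(cfg, make_protocol("IKS"), conditions, seed)
    norm = normalize_by_day(measure(dataset), "WT100_E1", cfg.reference_voltage_mV)
    est = classify_variant(
        norm, variant_id, "WITH_E1", zygosity, cfg.reference_voltage_mV
    )
    se = relative_amplitude_se(
        norm, label.value, "WT100_E1", cfg.reference_voltage_mV
    )
    return percent_reduction(est), 100.0 * se, est.n_oocytes


def noninjected_mean_nA(n_oocytes: int, seed: int) -> tuple[float, float, int]:
    """Mean end-of-step current of non-injected oocytes at +40 mV, in nA.

    Oocytes are spread over 8 recording days so the lognormal day effect
    averages out; the standard error is day-clustered (oocytes of one day
    share the batch multiplier, so the naive per-oocyte s.e. would be far
    too small).
    """
    n_days = 8
    per_day = n_oocytes // n_days
    cfg = GeneratorConfig(n_days=n_days, n_oocytes=per_day)
    proto = make_protocol("KCNQ1_ALONE")
    ds = generate_dataset(cfg, proto, [standard_condition("NONINJ")], seed)
    m = measure(ds)
    at40 = m[m["step_mV"] == 40.0]
    day_means = at40.groupby("day_id")["end_step_uA"].mean().to_numpy() * 1000.0
    se = float(day_means.std(ddof=1) / np.sqrt(day_means.size))
    n = int(len(at40))
    return float(at40["end_step_uA"].mean() * 1000.0), se, n


def apd90_percent_change(
    variant_id: str = "G119R",
    series: Series | str = Series.SHIFT_AND_SCALE,
    cell_type: CellType = CellType.EPI,
) -> float:
    """Limit-cycle APD90 change (%) of a variant vs wild-type at 2 Hz."""
    eff = variant_effect(variant_id, "WITH_E1", "HET")
    base = CellModelParams(cell_type)
    wt = pace_to_limit_cycle(base)
    var = pace_to_limit_cycle(apply_effect(base, eff, series))
    return apd_change(var, wt)


def ecg_qt_percent_change(
    variant_id: str = "G119R",
    series: Series | str = Series.SHIFT_AND_SCALE,
    spec: CableSpec | None = None,
    threshold_mV: float = 0.001,
    wildtype_result=None,
) -> float:
    """Cable pseudo-ECG QT change (%) of a variant vs wild-type.

    ``wildtype_result`` may pass a precomputed wild-type cable run for the
    same spec to avoid recomputation.
    """
    spec = spec or CableSpec()
    eff = variant_effect(variant_id, "WITH_E1", "HET")
    wt = wildtype_result or run_cable(spec, CellModelParams())
    qt_wt = measure_qt(wt.time_ms, pseudo_ecg(wt), threshold_mV)
    var = run_cable(spec, apply_effect(CellModelParams(), eff, series))
    qt_var = measure_qt(var.time_ms, pseudo_ecg(var), threshold_mV)
    return qt_percent_change(qt_var, qt_wt)
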