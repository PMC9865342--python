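"""Seeded synthetic two-electrode voltage-clamp datasets.

Emulates oocyte recordings of KCNQ1 / IKs currents across the full set of
expression conditions.  Each oocyte's current is the sum of three ohmic
components sharing a Boltzmann-gated, mono-exponentially activating
conductance model:

``I(t, V) = leak(V) + xIKs(t, V) + channel(t, V) + noise``

* ``channel`` — the exogenous (injected) KCNQ1 or IKs conductance,
  ``C * g_inf(V - dV1/2) * a(t) * (V - E_K) / (V_ref - E_K)``, where
  ``g_inf`` is a Boltzmann in voltage, ``a(t) = 1 - exp(-t/tau)`` during the
  step, and the tail deactivates mono-exponentially from the step-end gating
  level (the conductance is continuous across the step->tail transition; the
  recorded current jumps there because the driving force changes).
* ``xIKs`` — endogenous Xenopus IKs (KCNE1 co-assembling with native
  xKCNQ1), present whenever KCNE1 is injected; same gating as wild-type IKs.
* ``leak`` — endogenous background of every oocyte, linear in voltage,
  calibrated so non-injected oocytes pass ~150 nA at +40 mV.

Biological variability enters as lognormal multipliers: a per-day batch
effect shared by all components of that day's oocytes, a per-oocyte
expression factor on the exogenous and endogenous channel components, and a
per-oocyte leak factor.  Recording noise is additive Gaussian per sample.

The per-condition truth ``r_total`` is defined on the same scale the
downstream analysis estimates: the ratio of mean *total* end-of-step current
to the wild-type reference condition at the reference voltage.  The
generator solves for the exogenous-channel component (and, for conditions
dominant-negative on the endogenous current, a suppressed xIKs component)
that realizes the requested total.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .conditions import Condition, ConditionLabel
from .protocols import Protocol

__all__ = [
    "GatingParams",
    "ConditionTruth",
    "GeneratorConfig",
    "ClampDataset",
    "generate_dataset",
    "boltzmann",
    "expected_end_step_current",
    "condition_key",
]

END_WINDOW_MS = 50.0  # window over which "end-of-step" current is averaged


def boltzmann(v: np.ndarray | float, v_half: float, k: float) -> np.ndarray | float:
    """Steady-state activation 1 / (1 + exp((v_half - V)/k))."""
    return 1.0 / (1.0 + np.exp((v_half - np.asarray(v, dtype=float)) / k))


@dataclass(frozen=True)
class GatingParams:
    """Phenomenological gating of one channel population.

    v_half/slope in mV (Boltzmann steady state), activation and
    deactivation time constants in ms.
    """

    v_half_mV: float
    slope_mV: float
    tau_act_ms: float
    tau_deact_ms: float


@dataclass(frozen=True)
class ConditionTruth:
    """Generator ground truth for one condition.

    r_total : target day-normalized total current amplitude relative to the
        wild-type reference condition at the reference voltage (the twin of
        the analysis output r).  ``None`` marks background-only conditions.
    delta_v_half_mV : activation shift applied to the exogenous channel.
    """

    r_total: float | None
    delta_v_half_mV: float = 0.0

    def __post_init__(self) -> None:
        if self.r_total is not None and self.r_total < 0:
            raise ValueError("r_total must be nonnegative")


def condition_key(label: ConditionLabel | str, variant_id: str = "") -> str:
    label = ConditionLabel(label)
    return f"{label.value}:{variant_id}" if variant_id else label.value


_DEFAULT_TRUTHS = {
    "WT100": ConditionTruth(1.0),
    "WT50": ConditionTruth(0.5),
    "WT100_E1": ConditionTruth(1.0),
    "WT50_E1": ConditionTruth(0.5),
    "E1_ONLY": ConditionTruth(None),
    "NONINJ": ConditionTruth(None),
}


@dataclass
class GeneratorConfig:
    """Tunable parameters of the synthetic clamp-data generator.

    Amplitudes are mean total end-of-step currents (µA) of the wild-type
    reference condition at ``reference_voltage_mV``; variability parameters
    are coefficients of variation of lognormal multipliers.
    """

    wt_amplitude_no_e1_uA: float = 2.5
    wt_amplitude_e1_uA: float = 6.0
    reference_voltage_mV: float = 40.0
    noninjected_uA: float = 0.15  # leak current at +40 mV (~150 nA)
    xiks_fraction: float = 0.12  # endogenous xIKs vs WT100_E1 total
    reversal_mV: float = -90.0  # K+ reversal of expressed channels
    leak_reversal_mV: float = -40.0
    expression_cv: float = 0.25
    day_sd: float = 0.15
    leak_cv: float = 0.30
    noise_sd_uA: float = 0.02
    gating_no_e1: GatingParams = field(
        default_factory=lambda: GatingParams(-20.0, 12.0, 150.0, 120.0)
    )
    gating_e1: GatingParams = field(
        default_factory=lambda: GatingParams(20.0, 14.0, 2500.0, 400.0)
    )
    n_days: int = 3
    n_oocytes: int = 10
    truths: dict[str, ConditionTruth] = field(
        default_factory=lambda: dict(_DEFAULT_TRUTHS)
    )

    def __post_init__(self) -> None:
        for name in ("expression_cv", "day_sd", "leak_cv", "noise_sd_uA"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_days < 1 or self.n_oocytes < 1:
            raise ValueError("n_days and n_oocytes must be >= 1")

    def with_truth(
        self,
        label: ConditionLabel | str,
        variant_id: str,
        r_total: float,
        delta_v_half_mV: float = 0.0,
    ) -> "GeneratorConfig":
        """Copy of this config with one variant condition truth added."""
        truths = dict(self.truths)
        truths[condition_key(label, variant_id)] = ConditionTruth(
            r_total, delta_v_half_mV
        )
        return replace(self, truths=truths)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["truths"] = {
            k: {"r_total": t.r_total, "delta_v_half_mV": t.delta_v_half_mV}
            for k, t in self.truths.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in ("gating_no_e1", "gating_e1"):
            if key in d and isinstance(d[key], dict):
                d[key] = GatingParams(**d[key])
        if "truths" in d:
            d["truths"] = {
                k: ConditionTruth(**v) if isinstance(v, dict) else v
                for k, v in d["truths"].items()
            }
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# closed-form building blocks (also used by analytic oracles in the tests)
# ---------------------------------------------------------------------------


def _activation_mean_end(gating: GatingParams, step_ms: float, window: float = END_WINDOW_MS) -> float:
    """Mean of a(t) = 1 - exp(-t/tau) over the last ``window`` ms of the step."""
    tau = gating.tau_act_ms
    t0, t1 = step_ms - window, step_ms
    return 1.0 - tau / window * (np.exp(-t0 / tau) - np.exp(-t1 / tau))


def _gating_for(config: GeneratorConfig, label: ConditionLabel) -> GatingParams:
    return config.gating_e1 if label.with_kcne1 else config.gating_no_e1


def _wt_amplitude(config: GeneratorConfig, label: ConditionLabel) -> float:
    return (
        config.wt_amplitude_e1_uA if label.with_kcne1 else config.wt_amplitude_no_e1_uA
    )


def _leak_conductance(config: GeneratorConfig) -> float:
    """Leak conductance (µA/mV) anchored to the non-injected level at V_ref."""
    drive = config.reference_voltage_mV - config.leak_reversal_mV
    return config.noninjected_uA / drive


def _measured_unit_response(
    config: GeneratorConfig, gating: GatingParams, delta: float, step_ms: float
) -> float:
    """Expected end-of-step current at V_ref of a unit-scale channel."""
    g_inf = boltzmann(config.reference_voltage_mV - delta, gating.v_half_mV, gating.slope_mV)
    return float(g_inf) * _activation_mean_end(gating, step_ms)


@dataclass(frozen=True)
class _Components:
    """Conductance scales (µA at V_ref, full activation) for one condition."""

    channel_scale: float
    channel_gating: GatingParams
    channel_shift: float
    xiks_scale: float
    xiks_gating: GatingParams


def _solve_components(
    config: GeneratorConfig, condition: Condition, protocol: Protocol
) -> _Components:
    """Decompose a condition's target total current into components."""
    label = condition.label
    key = condition_key(label, condition.variant_id)
    if key not in config.truths:
        raise KeyError(
            f"no generator truth for condition '{key}'; add one with "
            "GeneratorConfig.with_truth()"
        )
    truth = config.truths[key]
    gating = _gating_for(config, label)
    leak_ref = config.noninjected_uA
    xiks_full = (
        config.xiks_fraction * config.wt_amplitude_e1_uA if label.with_kcne1 else 0.0
    )
    unit_x = (
        _measured_unit_response(config, config.gating_e1, 0.0, protocol.step_duration)
        if label.with_kcne1
        else 1.0
    )

    if truth.r_total is None:  # background-only condition
        return _Components(0.0, gating, 0.0, xiks_full / unit_x if xiks_full else 0.0,
                           config.gating_e1)

    target = truth.r_total * _wt_amplitude(config, label)
    if target < leak_ref:
        raise ValueError(
            f"condition '{key}': target total {target:.3f} µA is below the "
            f"leak background {leak_ref:.3f} µA"
        )
    channel_ref = target - leak_ref - xiks_full
    xiks_ref = xiks_full
    if channel_ref < 0:
        # total below the endogenous level: the variant suppresses xIKs too
        channel_ref = 0.0
        xiks_ref = target - leak_ref
    unit = _measured_unit_response(
        config, gating, truth.delta_v_half_mV, protocol.step_duration
    )
    return _Components(
        channel_scale=channel_ref / unit,
        channel_gating=gating,
        channel_shift=truth.delta_v_half_mV,
        xiks_scale=xiks_ref / unit_x if label.with_kcne1 else 0.0,
        xiks_gating=config.gating_e1,
    )


def _component_trace(
    t: np.ndarray,
    protocol: Protocol,
    v_step: float,
    scale: float,
    gating: GatingParams,
    shift: float,
    config: GeneratorConfig,
) -> np.ndarray:
    """Noise-free current trace of one gated component over one sweep."""
    if scale == 0.0:
        return np.zeros_like(t)
    drive_norm = config.reference_voltage_mV - config.reversal_mV
    g_inf = float(boltzmann(v_step - shift, gating.v_half_mV, gating.slope_mV))
    in_step = t < protocol.step_duration
    act = np.where(in_step, 1.0 - np.exp(-np.maximum(t, 0.0) / gating.tau_act_ms), 0.0)
    # conductance at step end, carried continuously into the tail
    act_end = g_inf * (1.0 - np.exp(-protocol.step_duration / gating.tau_act_ms))
    t_tail = t - protocol.step_duration
    tail_gate = np.where(~in_step, act_end * np.exp(-np.maximum(t_tail, 0.0) / gating.tau_deact_ms), 0.0)
    drive_step = (v_step - config.reversal_mV) / drive_norm
    drive_tail = (protocol.tail_potential - config.reversal_mV) / drive_norm
    return scale * (g_inf * act * drive_step + tail_gate * drive_tail)


def _leak_trace(
    t: np.ndarray, protocol: Protocol, v_step: float, g_leak: float, config: GeneratorConfig
) -> np.ndarray:
    in_step = t < protocol.step_duration
    v = np.where(in_step, v_step, protocol.tail_potential)
    return g_leak * (v - config.leak_reversal_mV)


def expected_end_step_current(
    config: GeneratorConfig, condition: Condition, protocol: Protocol, v_step: float
) -> float:
    """Population-mean end-of-step current (µA) for a condition at ``v_step``.

    Analytic expectation of the generated current averaged over the last
    50 ms of the step; all lognormal factors have mean one, so this is the
    exact mean of the generative model (noise averages to zero).
    """
    comp = _solve_components(config, condition, protocol)
    t = protocol.time_grid()
    trace = (
        _component_trace(t, protocol, v_step, comp.channel_scale,
                         comp.channel_gating, comp.channel_shift, config)
        + _component_trace(t, protocol, v_step, comp.xiks_scale,
                           comp.xiks_gating, 0.0, config)
        + _leak_trace(t, protocol, v_step, _leak_conductance(config), config)
    )
    end = (t >= protocol.step_duration - END_WINDOW_MS) & (t < protocol.step_duration)
    return float(trace[end].mean())


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------

CSV_COLUMNS = ["day_id", "oocyte_id", "condition", "variant_id", "step_mV", "t_ms", "current_uA"]


@dataclass
class ClampDataset:
    """Long-format clamp recordings plus provenance metadata."""

    df: pd.DataFrame
    protocol: Protocol
    config: GeneratorConfig | None
    seed: int | None

    def to_dir(self, path: str | Path) -> None:
        """Write clamp_data.csv and a metadata.json sidecar."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.df.to_csv(path / "clamp_data.csv", index=False)
        meta = {
            "protocol": asdict(self.protocol),
            "config": self.config.to_dict() if self.config else None,
            "config_hash": self.config.config_hash() if self.config else None,
            "seed": self.seed,
        }
        (path / "metadata.json").write_text(json.dumps(meta, indent=2, default=float))

    @classmethod
    def from_dir(cls, path: str | Path) -> "ClampDataset":
        path = Path(path)
        df = pd.read_csv(path / "clamp_data.csv", dtype={"variant_id": str}, keep_default_na=False)
        meta = json.loads((path / "metadata.json").read_text())
        proto = Protocol(**{**meta["protocol"],
                            "step_potentials": tuple(meta["protocol"]["step_potentials"])})
        cfg = GeneratorConfig.from_dict(meta["config"]) if meta.get("config") else None
        return cls(df=df, protocol=proto, config=cfg, seed=meta.get("seed"))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """n lognormal multipliers with mean exactly 1 and coefficient of variation cv."""
    if cv == 0.0:
        return np.ones(n)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=n)


def generate_dataset(
    config: GeneratorConfig,
    protocol: Protocol,
    conditions: list[Condition],
    seed: int,
) -> ClampDataset:
    """Generate a deterministic synthetic clamp dataset.

    Identical ``(config, seed)`` yield a bit-identical dataset.  Raises
    ``KeyError`` for conditions without generator truth.
    """
    rng = np.random.default_rng(seed)
    t = protocol.time_grid()
    n_t = t.size
    day_factors = _lognormal_factors(rng, config.day_sd, config.n_days)
    g_leak = _leak_conductance(config)

    records: list[pd.DataFrame] = []
    for condition in conditions:
        comp = _solve_components(config, condition, protocol)
        key = condition_key(condition.label, condition.variant_id)
        base_traces = {
            v: (
                _component_trace(t, protocol, v, comp.channel_scale,
                                 comp.channel_gating, comp.channel_shift, config),
                _component_trace(t, protocol, v, comp.xiks_scale,
                                 comp.xiks_gating, 0.0, config),
                _leak_trace(t, protocol, v, g_leak, config),
            )
            for v in protocol.step_potentials
        }
        for day in range(config.n_days):
            d = day_factors[day]
            expr = _lognormal_factors(rng, config.expression_cv, config.n_oocytes)
            leakf = _lognormal_factors(rng, config.leak_cv, config.n_oocytes)
            for i in range(config.n_oocytes):
                oocyte_id = f"{key}_d{day + 1}_o{i + 1}"
                for v in protocol.step_potentials:
                    chan, xiks, leak = base_traces[v]
                    current = d * (expr[i] * (chan + xiks) + leakf[i] * leak)
                    if config.noise_sd_uA > 0:
                        current = current + rng.normal(0.0, config.noise_sd_uA, n_t)
                    records.append(
                        pd.DataFrame(
                            {
                                "day_id": day + 1,
                                "oocyte_id": oocyte_id,
                                "condition": condition.label.value,
                                "variant_id": condition.variant_id,
                                "step_mV": v,
                                "t_ms": t,
                                "current_uA": current,
                            }
                        )
                    )
    df = pd.concat(records, ignore_index=True)
    return ClampDataset(df=df, protocol=protocol, config=config, seed=seed)
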