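"""Single-cell action-potential simulations with IKs variant perturbations.

A variant's electrophysiological effect — relative IKs amplitude r and
activation shift dV1/2, both measured in the heterozygous complex with
KCNE1 (the patient-relevant state) — is injected into the ventricular
myocyte model by shifting the IKs activation steady state by +dV1/2 and,
in the SHIFT_AND_SCALE series, additionally multiplying G_Ks by r.  Cells
are paced to their limit cycle (consecutive-beat APD90 change below a
tolerance) before the reported beat is taken.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from . import tt06
from .analysis import VariantEffect

__all__ = [
    "CellType",
    "Series",
    "CellModelParams",
    "PacingSpec",
    "APResult",
    "apply_effect",
    "pace_to_limit_cycle",
    "apd90",
    "apd_change",
]


class CellType(str, Enum):
    ENDO = "ENDO"
    EPI = "EPI"
    M = "M"

    @property
    def code(self) -> int:
        return {"ENDO": tt06.CELL_ENDO, "EPI": tt06.CELL_EPI, "M": tt06.CELL_M}[self.value]


class Series(str, Enum):
    """Which perturbation series to apply."""

    SHIFT_ONLY = "SHIFT_ONLY"
    SHIFT_AND_SCALE = "SHIFT_AND_SCALE"


@dataclass(frozen=True)
class CellModelParams:
    """Myocyte model parameters: cell type plus the IKs perturbation."""

    cell_type: CellType = CellType.EPI
    gks_scale: float = 1.0
    xs_shift_mV: float = 0.0

    def __post_init__(self) -> None:
        if self.gks_scale < 0:
            raise ValueError("gks_scale must be nonnegative")

    def vector(self) -> np.ndarray:
        return tt06.build_params(self.cell_type.code, self.gks_scale, self.xs_shift_mV)


@dataclass(frozen=True)
class PacingSpec:
    """Pacing protocol: 2 Hz by default, 1 ms / 52 pA/pF stimulus."""

    frequency_hz: float = 2.0
    stim_amplitude: float = 52.0  # pA/pF, depolarizing
    stim_duration_ms: float = 1.0
    max_beats: int = 500
    apd_tolerance_ms: float = 0.01

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError("frequency must be positive")
        if self.max_beats < 1:
            raise ValueError("max_beats must be >= 1")

    @property
    def cycle_length_ms(self) -> float:
        return 1000.0 / self.frequency_hz


@dataclass
class APResult:
    """Last-beat membrane potential and IKs time courses with APD90."""

    time_ms: np.ndarray
    vm_mV: np.ndarray
    iks: np.ndarray
    apd90_ms: float
    resting_vm_mV: float
    peak_vm_mV: float
    beats_to_converge: int
    converged: bool
    final_state: np.ndarray


def apply_effect(
    base: CellModelParams,
    effect: VariantEffect,
    series: Series | str = Series.SHIFT_AND_SCALE,
) -> CellModelParams:
    """Perturb the IKs of ``base`` according to a measured variant effect.

    Intended for effects from the heterozygous, KCNE1-containing context.
    A missing dV1/2 is treated as no shift.
    """
    series = Series(series)
    shift = effect.delta_v_half_mV
    if shift is None:
        import logging

        logging.getLogger(__name__).warning(
            "variant %s has no activation-shift estimate; using 0 mV",
            effect.variant_id,
        )
        shift = 0.0
    scale = effect.r if series is Series.SHIFT_AND_SCALE else 1.0
    return replace(base, gks_scale=base.gks_scale * scale,
                   xs_shift_mV=base.xs_shift_mV + shift)


def apd90(
    time_ms: np.ndarray, vm: np.ndarray, stimulus_time_ms: float = 0.0
) -> float:
    """Action potential duration at 90% repolarization.

    Amplitude is peak Vm minus the pre-stimulus (resting) Vm; APD90 runs
    from the time of maximum upstroke velocity to the first subsequent
    downward crossing of rest + 0.1*amplitude (linear interpolation).
    Raises ``ValueError`` if the trace never repolarizes to that level.
    """
    t = np.asarray(time_ms, dtype=float)
    v = np.asarray(vm, dtype=float)
    pre = v[t <= stimulus_time_ms]
    v_rest = float(pre[-1]) if pre.size else float(v[0])
    peak = float(v.max())
    amplitude = peak - v_rest
    if amplitude <= 0:
        raise ValueError("no action potential in trace")
    dvdt = np.diff(v) / np.diff(t)
    # end of the steepest rising interval; ties (e.g. a linear ramp) break
    # toward the latest interval so the upstroke ends at the peak
    i_up = int(np.flatnonzero(np.isclose(dvdt, dvdt.max(), rtol=1e-9, atol=1e-12))[-1])
    t_up = t[i_up + 1]
    level = v_rest + 0.1 * amplitude
    after = np.nonzero((t[1:] > t_up) & (v[1:] <= level) & (v[:-1] > level))[0]
    if after.size == 0:
        raise ValueError("no repolarization: Vm never crosses the APD90 level")
    i = int(after[0])
    # linear interpolation of the crossing time
    frac = (v[i] - level) / (v[i] - v[i + 1])
    t_cross = t[i] + frac * (t[i + 1] - t[i])
    return float(t_cross - t_up)


def pace_to_limit_cycle(
    params: CellModelParams,
    pacing: PacingSpec = PacingSpec(),
    dt_ms: float = 0.02,
    record_dt_ms: float = 0.1,
    initial_state: np.ndarray | None = None,
) -> APResult:
    """Pace the myocyte until APD90 converges; return the last beat.

    Beats are integrated one cycle at a time; pacing stops once the
    consecutive-beat APD90 difference has stayed below the tolerance for
    five beat pairs in a row, or at ``max_beats``.  (A single sub-tolerance
    difference is not enough: the beat-to-beat difference passes through
    zero at the turning point of the early rate-adaptation transient, long
    before the slow ionic drift has settled.)  Raises ``RuntimeError`` on
    failure to capture (peak Vm < 0 mV).
    """
    p = params.vector()
    s = tt06.INITIAL_STATE.copy() if initial_state is None else np.asarray(initial_state, dtype=float).copy()
    record_every = max(1, int(round(record_dt_ms / dt_ms)))
    cl = pacing.cycle_length_ms
    prev_apds: list[float] = []
    stable_pairs = 0
    converged = False
    beat = 0
    t = v = iks = None
    for beat in range(1, pacing.max_beats + 1):
        t, v, iks = tt06.run_beat(
            s, p, dt_ms, cl, pacing.stim_amplitude, pacing.stim_duration_ms,
            record_every,
        )
        if v.max() < 0.0:
            raise RuntimeError(f"no capture: peak Vm {v.max():.1f} mV < 0 mV on beat {beat}")
        try:
            apd = apd90(t, v)
        except ValueError as err:
            raise RuntimeError(f"solver/trace failure on beat {beat}: {err}") from err
        prev_apds.append(apd)
        if len(prev_apds) >= 2 and abs(prev_apds[-1] - prev_apds[-2]) < pacing.apd_tolerance_ms:
            stable_pairs += 1
            if stable_pairs >= 5:
                converged = True
                break
        else:
            stable_pairs = 0
    return APResult(
        time_ms=t,
        vm_mV=v,
        iks=iks,
        apd90_ms=prev_apds[-1],
        resting_vm_mV=float(v[0]),
        peak_vm_mV=float(v.max()),
        beats_to_converge=beat,
        converged=converged,
        final_state=s.copy(),
    )


def apd_change(variant: APResult, wildtype: APResult) -> float:
    """Percent APD90 change of a variant relative to wild-type."""
    return 100.0 * (variant.apd90_ms - wildtype.apd90_ms) / wildtype.apd90_ms
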