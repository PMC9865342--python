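"""Two-electrode voltage-clamp step protocols.

Xenopus oocyte recordings of KCNQ1 (alone) and IKs (KCNQ1 + KCNE1) use
families of depolarizing steps from a -80 mV holding potential.  KCNQ1
homotetramers activate within hundreds of milliseconds, so 3 s steps from
-60 to +60 mV suffice; the KCNE1-slowed IKs complex needs 7 s steps, taken
from -40 to +40 mV.  Every step is followed by a repolarizing tail step at
which the deactivating tail current is recorded; its peak indexes the
channels opened by the preceding step and yields the activation (G/V) curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = ["ProtocolKind", "Protocol", "make_protocol"]


class ProtocolKind(str, Enum):
    """Which expression context the voltage protocol targets."""

    KCNQ1_ALONE = "KCNQ1_ALONE"
    IKS = "IKS"


@dataclass(frozen=True)
class Protocol:
    """A step/tail voltage-clamp protocol.

    Attributes
    ----------
    holding_potential : float
        Holding potential between sweeps, mV.
    step_potentials : tuple of float
        Depolarizing test potentials, mV, strictly increasing.
    step_duration : float
        Duration of each test step, ms.
    tail_potential : float
        Potential of the repolarizing tail step, mV.
    tail_duration : float
        Duration of the tail step, ms.
    sample_interval : float
        Sampling interval of the digitized current, ms.
    """

    holding_potential: float
    step_potentials: tuple[float, ...]
    step_duration: float
    tail_potential: float
    tail_duration: float
    sample_interval: float = 10.0

    def __post_init__(self) -> None:
        steps = tuple(float(v) for v in self.step_potentials)
        object.__setattr__(self, "step_potentials", steps)
        if len(steps) < 1:
            raise ValueError("protocol needs at least one step potential")
        if any(b <= a for a, b in zip(steps, steps[1:])):
            raise ValueError("step_potentials must be strictly increasing")
        for name in ("step_duration", "tail_duration", "sample_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def sweep_duration(self) -> float:
        """Total duration of one sweep (step + tail), ms."""
        return self.step_duration + self.tail_duration

    def time_grid(self) -> np.ndarray:
        """Uniform sample times for one sweep, ms (0 = step onset)."""
        n = int(round(self.sweep_duration / self.sample_interval))
        return np.arange(n) * self.sample_interval


def make_protocol(kind: ProtocolKind | str, sample_interval: float = 10.0) -> Protocol:
    """Build the standard protocol for a given expression context.

    ``KCNQ1_ALONE``: 3 s steps, -60 to +60 mV in 20 mV increments.
    ``IKS``: 7 s steps, -40 to +40 mV in 20 mV increments.
    Both hold at -80 mV and append a 1 s tail step at -40 mV.
    """
    kind = ProtocolKind(kind)
    if kind is ProtocolKind.KCNQ1_ALONE:
        steps = tuple(np.arange(-60.0, 61.0, 20.0))
        step_ms = 3000.0
    else:
        steps = tuple(np.arange(-40.0, 41.0, 20.0))
        step_ms = 7000.0
    return Protocol(
        holding_potential=-80.0,
        step_potentials=steps,
        step_duration=step_ms,
        tail_potential=-40.0,
        tail_duration=1000.0,
        sample_interval=sample_interval,
    )
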