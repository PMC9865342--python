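import numpy as np
import pandas as pd
import pytest

from iksvar.cell_model import CellModelParams, CellType, pace_to_limit_cycle
from iksvar.conditions import standard_condition
from iksvar.generator import ClampDataset, GeneratorConfig, generate_dataset
from iksvar.protocols import make_protocol


@pytest.fixture(scope="session")
def iks_protocol():
    return make_protocol("IKS")


@pytest.fixture(scope="session")
def het_dataset(iks_protocol):
    """Default-size G119R het + KCNE1 dataset (3 days x 10 oocytes), seed 1."""
    cfg = GeneratorConfig().with_truth("HET_E1", "G119R", 0.74, 0.0)
    conds = [
        standard_condition("WT100_E1"),
        standard_condition("HET_E1", "G119R"),
        standard_condition("E1_ONLY"),
    ]
    return generate_dataset(cfg, iks_protocol, conds, seed=1)


def make_flat_dataset(protocol, current=1.0, tail_current=None, spike=None):
    """Hand-built single-oocyte dataset with constant step/tail currents.

    ``spike``: optional (t_offset_after_step_ms, value) inserted into the
    tail to exercise capacitance blanking.
    """
    t = protocol.time_grid()
    rows = []
    for v in protocol.step_potentials:
        cur = np.full_like(t, float(current))
        if tail_current is not None:
            cur[t >= protocol.step_duration] = tail_current
        if spike is not None:
            dt_off, val = spike
            idx = np.argmin(np.abs(t - (protocol.step_duration + dt_off)))
            cur[idx] = val
        rows.append(
            pd.DataFrame(
                {
                    "day_id": 1,
                    "oocyte_id": "o1",
                    "condition": "WT100_E1",
                    "variant_id": "",
                    "step_mV": v,
                    "t_ms": t,
                    "current_uA": cur,
                }
            )
        )
    return ClampDataset(pd.concat(rows, ignore_index=True), protocol, None, None)


class ApCache:
    """Memoized limit-cycle runs keyed by (gks_scale, xs_shift)."""

    def __init__(self):
        self._runs = {}

    def get(self, gks_scale=1.0, xs_shift=0.0, cell_type=CellType.EPI):
        key = (round(gks_scale, 6), round(xs_shift, 6), cell_type)
        if key not in self._runs:
            self._runs[key] = pace_to_limit_cycle(
                CellModelParams(cell_type, gks_scale, xs_shift)
            )
        return self._runs[key]


@pytest.fixture(scope="session")
def ap_cache():
    return ApCache()


@pytest.fixture(scope="session")
def default_wt_cable():
    """Wild-type cable at full default conditioning (20 beats)."""
    from iksvar.pseudo_ecg import CableSpec, run_cable

    return run_cable(CableSpec(), CellModelParams())
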