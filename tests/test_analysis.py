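"""Measurement, normalization, statistics and classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from iksvar.analysis import (
    build_iv,
    classify_variant,
    fit_activation,
    measure,
    normalize_by_day,
    percent_reduction,
    relative_amplitude_se,
    significance_stars,
    ttest,
)
from iksvar.conditions import standard_condition
from iksvar.generator import GeneratorConfig, generate_dataset
from tests.conftest import make_flat_dataset


def small_norm_table(groups: dict[str, list[float]], voltage=40.0) -> pd.DataFrame:
    """Hand-built day-normalized measurement table for classification tests."""
    rows = []
    for cond, vals in groups.items():
        for i, v in enumerate(vals):
            rows.append(
                {
                    "day_id": 1,
                    "oocyte_id": f"{cond}_{i}",
                    "condition": cond,
                    "variant_id": "VAR" if cond in ("HET", "HET_E1", "VAR100", "VAR100_E1") else "",
                    "step_mV": voltage,
                    "end_step_uA": v,
                    "normalized": v,
                }
            )
    return pd.DataFrame(rows)


class TestMeasure:
    def test_constant_trace(self, iks_protocol):
        ds = make_flat_dataset(iks_protocol, current=1.0)
        m = measure(ds)
        assert (m["end_step_uA"] == 1.0).all()

    def test_tail_spike_blanked(self, iks_protocol):
        ds = make_flat_dataset(iks_protocol, current=1.0, tail_current=0.3,
                               spike=(0.0, 50.0))
        m = measure(ds, blank_ms=10.0)
        assert (m["tail_peak_uA"] == 0.3).all()

    def test_incomplete_oocyte_rejected(self, iks_protocol, caplog):
        ds = make_flat_dataset(iks_protocol, current=1.0)
        truncated = ds.df[ds.df["t_ms"] < 5000.0]
        ds.df = truncated
        with caplog.at_level("WARNING"):
            m = measure(ds)
        assert m.empty
        assert "rejecting oocyte" in caplog.text

    def test_generated_trace_matches_analytic_formula(self, het_dataset):
        """End-of-step currents agree with the generative closed form.

        The noise-free expectation is checked through the zero-variance path
        in the generator tests; here the default-noise dataset must land
        within a few noise s.d. of its own trace mean (5 samples averaged).
        """
        from iksvar.generator import expected_end_step_current

        m = measure(het_dataset)
        cfg = het_dataset.config
        cond = standard_condition("HET_E1", "G119R")
        got = m[(m["condition"] == "HET_E1") & (m["step_mV"] == 40.0)]["end_step_uA"]
        expected = expected_end_step_current(cfg, cond, het_dataset.protocol, 40.0)
        # population mean over 30 oocytes: dominated by expression CV
        se = got.std(ddof=1) / np.sqrt(len(got))
        assert abs(got.mean() - expected) < 3 * se


class TestNormalization:
    def test_single_day_ratio(self):
        m = small_norm_table({"WT100_E1": [2.0, 2.0], "HET_E1": [1.0]})
        out = normalize_by_day(m.drop(columns="normalized"), "WT100_E1", 40.0)
        het = out[out["condition"] == "HET_E1"]["normalized"]
        assert het.iloc[0] == pytest.approx(0.5)

    def test_day_effect_cancels(self):
        rows = []
        for day, wt_mean in ((1, 1.0), (2, 4.0)):
            for i, (cond, frac) in enumerate(
                [("WT100_E1", 1.0), ("WT100_E1", 1.0), ("HET_E1", 0.6), ("HET_E1", 0.8)]
            ):
                rows.append(
                    {
                        "day_id": day,
                        "oocyte_id": f"d{day}o{i}",
                        "condition": cond,
                        "variant_id": "",
                        "step_mV": 40.0,
                        "end_step_uA": wt_mean * frac,
                    }
                )
        out = normalize_by_day(pd.DataFrame(rows), "WT100_E1", 40.0)
        per_day = out[out["condition"] == "HET_E1"].groupby("day_id")["normalized"].mean()
        assert per_day.loc[1] == pytest.approx(per_day.loc[2])

    def test_missing_reference_day_raises(self):
        m = small_norm_table({"HET_E1": [1.0, 2.0]})
        with pytest.raises(ValueError, match="lack reference"):
            normalize_by_day(m.drop(columns="normalized"), "WT100_E1", 40.0)

    def test_reference_anchor_exact(self, het_dataset):
        norm = normalize_by_day(measure(het_dataset), "WT100_E1", 40.0)
        ref = norm[(norm["condition"] == "WT100_E1") & (norm["step_mV"] == 40.0)]
        assert ref["normalized"].mean() == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=20, derandomize=True)
    @given(scale=st.floats(min_value=0.01, max_value=100.0, allow_nan=False))
    def test_day_rescaling_invariance(self, scale):
        """Multiplying one day's currents by any constant changes nothing."""
        rows = []
        rng = np.random.default_rng(0)
        for day in (1, 2):
            for cond in ("WT100_E1", "HET_E1"):
                for i in range(4):
                    rows.append(
                        {
                            "day_id": day,
                            "oocyte_id": f"{cond}d{day}o{i}",
                            "condition": cond,
                            "variant_id": "",
                            "step_mV": 40.0,
                            "end_step_uA": rng.uniform(0.5, 3.0),
                        }
                    )
        m = pd.DataFrame(rows)
        base = normalize_by_day(m, "WT100_E1", 40.0)
        m2 = m.copy()
        m2.loc[m2["day_id"] == 2, "end_step_uA"] *= scale
        scaled = normalize_by_day(m2, "WT100_E1", 40.0)
        np.testing.assert_allclose(
            base["normalized"], scaled["normalized"], rtol=1e-10
        )


class TestIVCurve:
    def test_anchor_and_sem(self):
        m = small_norm_table({"WT100_E1": [1.0, 1.0], "HET_E1": [0.5, 0.5]})
        iv = build_iv(m, "HET_E1", "WT100_E1", 40.0)
        assert iv.normalized_mean == (0.5,)
        assert iv.sem == (0.0,)
        assert iv.n == 2

    def test_round_trip_recovers_r_true(self, het_dataset):
        norm = normalize_by_day(measure(het_dataset), "WT100_E1", 40.0)
        iv = build_iv(norm, "HET_E1", "WT100_E1", 40.0)
        i40 = iv.voltages.index(40.0)
        se = relative_amplitude_se(norm, "HET_E1", "WT100_E1", 40.0)
        assert abs(iv.normalized_mean[i40] - 0.74) < 2 * se

    def test_needs_two_oocytes(self):
        m = small_norm_table({"HET_E1": [0.5]})
        with pytest.raises(ValueError, match=">= 2 oocytes"):
            build_iv(m, "HET_E1", "WT100_E1", 40.0)


class TestTTest:
    def test_identical_groups(self):
        res = ttest([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.t_statistic == 0.0 and res.p_value == 1.0

    def test_closed_form_example(self):
        """{1,2,3} vs {4,5,6}: pooled s^2 = 1, t = -3/sqrt(2/3), df = 4."""
        from scipy.stats import t as t_dist

        res = ttest([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        t_expected = -3.0 / math.sqrt(2.0 / 3.0)
        p_expected = 2.0 * t_dist.sf(abs(t_expected), df=4)
        assert res.t_statistic == pytest.approx(t_expected, rel=1e-12)
        assert res.p_value == pytest.approx(p_expected, rel=1e-12)

    @settings(max_examples=25, derandomize=True)
    @given(
        a=st.lists(st.floats(-10, 10), min_size=2, max_size=8),
        b=st.lists(st.floats(-10, 10), min_size=2, max_size=8),
    )
    def test_symmetry(self, a, b):
        r1 = ttest(a, b)
        r2 = ttest(b, a)
        assert r1.t_statistic == pytest.approx(-r2.t_statistic, abs=1e-9)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    @pytest.mark.parametrize(
        "p,stars",
        [(0.0005, "***"), (0.005, "**"), (0.03, "*"), (0.2, ""), (0.05, "")],
    )
    def test_star_mapping(self, p, stars):
        assert significance_stars(p) == stars


class TestClassification:
    def test_dominant_negative_het_no_e1(self):
        m = small_norm_table(
            {
                "WT100": [1.0, 1.05, 0.95, 1.1],
                "WT50": [0.5, 0.55, 0.45, 0.52],
                "HET": [0.30, 0.33, 0.28, 0.35],
            }
        )
        eff = classify_variant(m, "VAR", "NO_E1", "HET", 40.0)
        assert eff.loss_of_function and eff.dominant_negative
        assert not eff.gain_of_function

    def test_gain_of_function(self):
        m = small_norm_table(
            {"WT100": [1.0, 1.1, 0.9, 1.0], "VAR100": [1.6, 1.5, 1.7, 1.55]}
        )
        eff = classify_variant(m, "VAR", "NO_E1", "HOMO", 40.0)
        assert eff.gain_of_function and not eff.loss_of_function
        assert eff.r > 1 and eff.percent_change < 0

    def test_below_endogenous_homo_with_e1(self):
        m = small_norm_table(
            {
                "WT100_E1": [1.0, 1.02, 0.98],
                "E1_ONLY": [0.15, 0.14, 0.16],
                "VAR100_E1": [0.05, 0.06, 0.04],
            }
        )
        eff = classify_variant(m, "VAR", "WITH_E1", "HOMO", 40.0)
        assert eff.below_endogenous and eff.loss_of_function

    def test_null_variant_no_flags(self):
        rng = np.random.default_rng(1)
        m = small_norm_table(
            {
                "WT100_E1": list(1 + 0.05 * rng.standard_normal(8)),
                "HET_E1": list(1 + 0.05 * rng.standard_normal(8)),
            }
        )
        eff = classify_variant(m, "VAR", "WITH_E1", "HET", 40.0)
        assert not (eff.loss_of_function or eff.gain_of_function)
        assert eff.r == pytest.approx(1.0, abs=0.1)

    def test_missing_control_raises(self):
        m = small_norm_table({"HET_E1": [0.5, 0.6]})
        with pytest.raises(ValueError, match="WT100_E1"):
            classify_variant(m, "VAR", "WITH_E1", "HET", 40.0)

    @pytest.mark.parametrize("r,pct", [(1.0, 0.0), (0.74, 26.0), (0.34, 66.0)])
    def test_percent_reduction(self, r, pct):
        from iksvar.analysis import VariantEffect

        eff = VariantEffect("v", "WITH_E1", "HET", r, 100 * (1 - r), 0.0, 40.0)
        assert percent_reduction(eff) == pytest.approx(pct)


class TestActivationRecovery:
    def test_v_half_estimator_consistency(self, iks_protocol):
        """Noisy per-oocyte V1/2 averages match the noise-free estimand.

        The max-normalized Boltzmann fit over -40..+40 mV has a systematic
        offset relative to the underlying gating midpoint (the channel is
        not saturated at +40 mV), so consistency is asserted against the
        fit of the noise-free closed-form tails, within 2 mV.
        """
        shift = 8.0
        cfg = GeneratorConfig().with_truth("HET_E1", "V", 0.6, shift)
        conds = [standard_condition("WT100_E1"), standard_condition("HET_E1", "V")]
        ds = generate_dataset(cfg, iks_protocol, conds, seed=21)
        m = measure(ds)
        noiseless_cfg = GeneratorConfig(
            expression_cv=0.0, day_sd=0.0, leak_cv=0.0, noise_sd_uA=0.0,
            n_days=1, n_oocytes=1,
        ).with_truth("HET_E1", "V", 0.6, shift)
        ds0 = generate_dataset(noiseless_cfg, iks_protocol, conds, seed=1)
        m0 = measure(ds0)
        for cond in ("WT100_E1", "HET_E1"):
            fit = fit_activation(m, cond)
            fit0 = fit_activation(m0, cond)
            assert abs(fit.v_half_mV - fit0.v_half_mV) < 2.0
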