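"""Analysis of voltage-clamp datasets: amplitudes, normalization, activation
fits, statistics, and functional classification of KCNQ1 variants.

The measurement pipeline mirrors standard oocyte practice: current amplitude
is read at the end of each voltage step (mean of the last 50 ms); the peak
tail current after each step indexes channel activation.  Amplitudes are
normalized per recording day to the wild-type reference condition, which
cancels batch-to-batch expression differences.  Activation (G/V) curves are
built from per-oocyte tail currents normalized to that oocyte's maximum and
fitted with a Boltzmann; V1/2 is averaged across oocytes.  Group comparisons
use the two-tailed equal-variance (Student's) t-test, without
multiple-testing correction.

Functional classification at the analysis voltage:

* loss/gain of function — variant vs full-dose wild-type (p < 0.05);
* dominant negative (heterozygous, no KCNE1) — het mix below the half-dose
  wild-type (haploinsufficiency) control;
* below endogenous (homomeric, with KCNE1) — variant + KCNE1 below the
  KCNE1-alone (endogenous xIKs) control, i.e. dominant negative on the
  native xKCNQ1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .generator import END_WINDOW_MS, ClampDataset, boltzmann

__all__ = [
    "measure",
    "normalize_by_day",
    "IVCurve",
    "build_iv",
    "BoltzmannFit",
    "fit_boltzmann",
    "ActivationFit",
    "fit_activation",
    "ComparisonResult",
    "ttest",
    "significance_stars",
    "VariantEffect",
    "classify_variant",
    "percent_reduction",
]

log = logging.getLogger(__name__)

K_BOUNDS = (1.0, 40.0)  # Boltzmann slope-factor fit bounds, mV


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------


def measure(dataset: ClampDataset, blank_ms: float = 10.0) -> pd.DataFrame:
    """Per-oocyte, per-step amplitude table.

    Returns columns day_id, oocyte_id, condition, variant_id, step_mV,
    end_step_uA (mean of the last 50 ms of the step) and tail_peak_uA
    (signed extremum of the tail after discarding the first ``blank_ms``,
    which blanks the capacitive transient).  Oocytes whose traces do not
    cover the full protocol are rejected with a logged reason.
    """
    proto = dataset.protocol
    df = dataset.df
    t_last = proto.sweep_duration - proto.sample_interval
    end_lo = proto.step_duration - END_WINDOW_MS
    tail_lo = proto.step_duration + blank_ms

    rows = []
    for (day, oocyte, cond, variant), g in df.groupby(
        ["day_id", "oocyte_id", "condition", "variant_id"], sort=True
    ):
        steps = set(g["step_mV"].unique())
        if not set(proto.step_potentials) <= steps or g["t_ms"].max() < t_last:
            log.warning(
                "rejecting oocyte %s: incomplete protocol coverage", oocyte
            )
            continue
        for v, tr in g.groupby("step_mV"):
            tt = tr["t_ms"].to_numpy()
            cur = tr["current_uA"].to_numpy()
            end_mask = (tt >= end_lo) & (tt < proto.step_duration)
            tail_mask = tt >= tail_lo
            tail = cur[tail_mask]
            tail_peak = float(tail[np.argmax(np.abs(tail))]) if tail.size else math.nan
            rows.append(
                {
                    "day_id": day,
                    "oocyte_id": oocyte,
                    "condition": cond,
                    "variant_id": variant,
                    "step_mV": float(v),
                    "end_step_uA": float(cur[end_mask].mean()),
                    "tail_peak_uA": tail_peak,
                }
            )
    return pd.DataFrame(rows)


def normalize_by_day(
    measurements: pd.DataFrame,
    reference_condition: str,
    reference_voltage: float,
) -> pd.DataFrame:
    """Divide amplitudes by each day's mean reference amplitude.

    Every oocyte's end-of-step currents are divided by the mean
    ``reference_condition`` current at ``reference_voltage`` of its
    recording day; a final global rescale pins the pooled normalized mean of
    the reference condition at the reference voltage to exactly 1.  Raises
    ``ValueError`` naming any day that lacks reference oocytes.
    """
    out = measurements.copy()
    ref = out[
        (out["condition"] == reference_condition)
        & (out["step_mV"] == reference_voltage)
    ]
    missing = sorted(set(out["day_id"]) - set(ref["day_id"]))
    if missing:
        raise ValueError(
            f"day(s) {missing} lack reference condition '{reference_condition}' "
            f"oocytes at {reference_voltage:+.0f} mV"
        )
    day_means = ref.groupby("day_id")["end_step_uA"].mean()
    out["normalized"] = out["end_step_uA"] / out["day_id"].map(day_means).to_numpy()
    pooled = out.loc[ref.index, "normalized"].mean()
    out["normalized"] /= pooled
    return out


# ---------------------------------------------------------------------------
# I/V curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IVCurve:
    """Mean +/- SEM normalized current-voltage relationship of one condition."""

    condition: str
    voltages: tuple[float, ...]
    normalized_mean: tuple[float, ...]
    sem: tuple[float, ...]
    n: int
    reference_condition: str
    reference_voltage: float


def build_iv(
    normalized: pd.DataFrame,
    condition: str,
    reference_condition: str,
    reference_voltage: float,
) -> IVCurve:
    """Build the I/V curve of ``condition`` from a day-normalized table."""
    sub = normalized[normalized["condition"] == condition]
    n = sub["oocyte_id"].nunique()
    if n < 2:
        raise ValueError(f"condition '{condition}' needs >= 2 oocytes, has {n}")
    g = sub.groupby("step_mV")["normalized"]
    means = g.mean()
    sems = g.std(ddof=1) / np.sqrt(g.count())
    return IVCurve(
        condition=condition,
        voltages=tuple(means.index),
        normalized_mean=tuple(means),
        sem=tuple(sems),
        n=n,
        reference_condition=reference_condition,
        reference_voltage=reference_voltage,
    )


# ---------------------------------------------------------------------------
# Boltzmann activation fits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoltzmannFit:
    v_half_mV: float
    slope_mV: float
    residual: float
    ok: bool
    reason: str = ""


def fit_boltzmann(
    voltages: np.ndarray | list[float], tails: np.ndarray | list[float]
) -> BoltzmannFit:
    """Least-squares Boltzmann fit of one oocyte's normalized tail currents.

    Tails are normalized to the oocyte's maximum tail before fitting
    G(V) = 1/(1 + exp((V1/2 - V)/k)); the slope factor is bounded in
    [1, 40] mV and fits pinned at a slope bound or otherwise degenerate are
    flagged ``ok=False`` so the caller can exclude them from averaging.
    """
    v = np.asarray(voltages, dtype=float)
    y = np.asarray(tails, dtype=float)
    if v.size < 4 or not np.all(np.isfinite(y)):
        return BoltzmannFit(math.nan, math.nan, math.nan, False, "need >=4 finite tails")
    ymax = np.max(np.abs(y))
    if ymax <= 0 or np.ptp(y) < 1e-9 * max(ymax, 1.0):
        return BoltzmannFit(math.nan, math.nan, math.nan, False, "non-identifiable: flat tails")
    yn = y / ymax
    v_lo, v_hi = v.min() - 40.0, v.max() + 40.0
    try:
        popt, _ = optimize.curve_fit(
            boltzmann,
            v,
            yn,
            p0=[float(np.median(v)), 10.0],
            bounds=([v_lo, K_BOUNDS[0]], [v_hi, K_BOUNDS[1]]),
            maxfev=10000,
        )
    except RuntimeError as err:
        return BoltzmannFit(math.nan, math.nan, math.nan, False, f"no convergence: {err}")
    v_half, k = float(popt[0]), float(popt[1])
    resid = float(np.sqrt(np.mean((boltzmann(v, v_half, k) - yn) ** 2)))
    eps = 1e-6
    if k <= K_BOUNDS[0] + eps or k >= K_BOUNDS[1] - eps:
        return BoltzmannFit(v_half, k, resid, False, "slope pinned at bound")
    return BoltzmannFit(v_half, k, resid, True)


@dataclass(frozen=True)
class ActivationFit:
    """Per-condition activation parameters, averaged over per-oocyte fits."""

    condition: str
    v_half_mV: float
    slope_mV: float
    residual: float
    n_oocytes: int
    per_oocyte_v_half: tuple[float, ...]


def fit_activation(measurements: pd.DataFrame, condition: str) -> ActivationFit:
    """Fit each oocyte's tail-current G/V curve; average V1/2 across oocytes."""
    sub = measurements[measurements["condition"] == condition]
    v_halves, slopes, resids = [], [], []
    for oocyte, g in sub.groupby("oocyte_id"):
        g = g.sort_values("step_mV")
        fit = fit_boltzmann(g["step_mV"].to_numpy(), g["tail_peak_uA"].to_numpy())
        if fit.ok:
            v_halves.append(fit.v_half_mV)
            slopes.append(fit.slope_mV)
            resids.append(fit.residual)
        else:
            log.warning("excluding oocyte %s from V1/2 averaging: %s", oocyte, fit.reason)
    if not v_halves:
        raise ValueError(f"no oocyte of condition '{condition}' yielded a valid activation fit")
    return ActivationFit(
        condition=condition,
        v_half_mV=float(np.mean(v_halves)),
        slope_mV=float(np.mean(slopes)),
        residual=float(np.mean(resids)),
        n_oocytes=len(v_halves),
        per_oocyte_v_half=tuple(v_halves),
    )


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def significance_stars(p: float) -> str:
    """Star notation: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class ComparisonResult:
    labels: tuple[str, str]
    means: tuple[float, float]
    sems: tuple[float, float]
    ns: tuple[int, int]
    t_statistic: float
    p_value: float
    stars: str


def ttest(
    group_a: np.ndarray | list[float],
    group_b: np.ndarray | list[float],
    labels: tuple[str, str] = ("a", "b"),
) -> ComparisonResult:
    """Two-tailed equal-variance (Student's) two-sample t-test."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        if a.mean() == b.mean():
            t_stat, p = 0.0, 1.0
        else:
            t_stat = math.inf if a.mean() > b.mean() else -math.inf
            p = 0.0
    else:
        res = stats.ttest_ind(a, b, equal_var=True)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return ComparisonResult(
        labels=labels,
        means=(float(a.mean()), float(b.mean())),
        sems=(float(a.std(ddof=1) / np.sqrt(a.size)), float(b.std(ddof=1) / np.sqrt(b.size))),
        ns=(a.size, b.size),
        t_statistic=t_stat,
        p_value=p,
        stars=significance_stars(p),
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

ALPHA = 0.05  # two-tailed significance threshold for all functional flags


@dataclass
class VariantEffect:
    """Functional effect of one variant in one expression context."""

    variant_id: str
    context: str  # NO_E1 | WITH_E1
    zygosity: str  # HOMO | HET
    r: float  # relative amplitude variant/WT at the analysis voltage
    percent_change: float  # 100*(1 - r) for r <= 1 (reduction), negative if GOF
    delta_v_half_mV: float | None
    analysis_voltage_mV: float
    loss_of_function: bool = False
    gain_of_function: bool = False
    dominant_negative: bool | None = None
    below_endogenous: bool | None = None
    p_values: dict = field(default_factory=dict)
    n_oocytes: int = 0
    source: str = "measured"

    def to_dict(self) -> dict:
        return asdict(self)


def percent_reduction(effect: VariantEffect) -> float:
    """Percent current reduction 100*(1 - r)."""
    return 100.0 * (1.0 - effect.r)


def relative_amplitude_se(
    normalized: pd.DataFrame,
    variant_condition: str,
    reference_condition: str,
    analysis_voltage: float,
) -> float:
    """Delta-method standard error of the amplitude ratio r.

    Treats the variant and reference groups of day-normalized amplitudes as
    independent: se(r)^2 ~ r^2 * (se_v^2/mean_v^2 + se_w^2/mean_w^2).
    """
    def _vals(cond: str) -> np.ndarray:
        return normalized[
            (normalized["condition"] == cond)
            & (normalized["step_mV"] == analysis_voltage)
        ]["normalized"].to_numpy()

    v = _vals(variant_condition)
    w = _vals(reference_condition)
    r = v.mean() / w.mean()
    rel_v = v.std(ddof=1) / np.sqrt(v.size) / v.mean()
    rel_w = w.std(ddof=1) / np.sqrt(w.size) / w.mean()
    return float(abs(r) * np.hypot(rel_v, rel_w))


def _variant_condition(context: str, zygosity: str) -> str:
    table = {
        ("NO_E1", "HOMO"): "VAR100",
        ("NO_E1", "HET"): "HET",
        ("WITH_E1", "HOMO"): "VAR100_E1",
        ("WITH_E1", "HET"): "HET_E1",
    }
    return table[(context, zygosity)]


def classify_variant(
    normalized: pd.DataFrame,
    variant_id: str,
    context: str,
    zygosity: str,
    analysis_voltage: float,
    delta_v_half_mV: float | None = None,
) -> VariantEffect:
    """Classify one variant's functional effect from a day-normalized table.

    Requires the matching variant condition plus the WT100(_E1) control;
    the dominant-negative call (HET, no KCNE1) additionally needs WT50, and
    the below-endogenous call (HOMO, with KCNE1) needs E1_ONLY.  The
    activation shift is not computed here: pass a value obtained from
    :func:`fit_activation` differences (positive = depolarizing shift).
    """
    with_e1 = context == "WITH_E1"
    wt_label = "WT100_E1" if with_e1 else "WT100"
    var_label = _variant_condition(context, zygosity)

    def _group(label: str) -> np.ndarray:
        vals = normalized[
            (normalized["condition"] == label)
            & (normalized["step_mV"] == analysis_voltage)
        ]["normalized"].to_numpy()
        if vals.size == 0:
            raise ValueError(f"missing control/variant condition '{label}' at "
                             f"{analysis_voltage:+.0f} mV")
        return vals

    var_vals = _group(var_label)
    wt_vals = _group(wt_label)
    cmp_wt = ttest(var_vals, wt_vals, labels=(var_label, wt_label))
    r = float(var_vals.mean() / wt_vals.mean())
    p_values = {"vs_WT100": cmp_wt.p_value}
    lof = bool(cmp_wt.p_value < ALPHA and var_vals.mean() < wt_vals.mean())
    gof = bool(cmp_wt.p_value < ALPHA and var_vals.mean() > wt_vals.mean())

    dominant_negative: bool | None = None
    if zygosity == "HET" and not with_e1:
        wt50 = _group("WT50")
        cmp50 = ttest(var_vals, wt50, labels=(var_label, "WT50"))
        p_values["vs_WT50"] = cmp50.p_value
        dominant_negative = bool(
            cmp50.p_value < ALPHA and var_vals.mean() < wt50.mean()
        )

    below_endogenous: bool | None = None
    if zygosity == "HOMO" and with_e1:
        xiks = _group("E1_ONLY")
        cmpx = ttest(var_vals, xiks, labels=(var_label, "E1_ONLY"))
        p_values["vs_E1_ONLY"] = cmpx.p_value
        below_endogenous = bool(
            cmpx.p_value < ALPHA and var_vals.mean() < xiks.mean()
        )

    return VariantEffect(
        variant_id=variant_id,
        context=context,
        zygosity=zygosity,
        r=r,
        percent_change=100.0 * (1.0 - r),
        delta_v_half_mV=None if delta_v_half_mV is None else float(delta_v_half_mV),
        analysis_voltage_mV=analysis_voltage,
        loss_of_function=lof,
        gain_of_function=gof,
        dominant_negative=dominant_negative,
        below_endogenous=below_endogenous,
        p_values=p_values,
        n_oocytes=int(var_vals.size),
    )
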