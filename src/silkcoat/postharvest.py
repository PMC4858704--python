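"""Fruit postharvest physiology metrics: respiration rate, dehydration,
firmness, and the group-comparison statistics used to judge coating effects.

Respiration is measured in a closed jar: fruit of mass m (kg) in a hermetic
vessel of free headspace V (ml) accumulates CO2; the rate is

    R = (dCO2/100 * V) / (m * dt)     [ml CO2 kg^-1 h^-1]

with dCO2 the percentage-point rise over the chosen window and dt in hours.
Dehydration is the fraction of the day-0 weight lost; firmness is the
maximum force recorded while a 5 mm flat probe penetrates the fruit to 8 mm.
Group comparisons use one-way (default) or two-way ANOVA with Tukey HSD
pairwise testing at alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import ValidationError

__all__ = [
    "HeadspaceSeries",
    "WeightSeries",
    "PunctureCurve",
    "respiration_rate",
    "weight_loss_fraction",
    "max_penetration_force",
    "firmness_summary",
    "group_compare",
]


@dataclass
class HeadspaceSeries:
    """Jar headspace CO2 record: hours vs percent v/v, with fruit mass (kg)
    and free headspace volume (ml) — the jar volume minus the fruit."""

    t_h: np.ndarray
    co2_pct: np.ndarray
    mass_kg: float
    headspace_ml: float
    replicate_id: str = ""

    def __post_init__(self):
        self.t_h = np.asarray(self.t_h, dtype=float)
        self.co2_pct = np.asarray(self.co2_pct, dtype=float)
        if self.t_h.shape != self.co2_pct.shape or self.t_h.ndim != 1:
            raise ValidationError("t_h and co2_pct must be matching 1-D arrays")
        if not np.all(np.diff(self.t_h) > 0):
            raise ValidationError("time stamps must be strictly increasing")
        if self.mass_kg <= 0 or self.headspace_ml <= 0:
            raise ValidationError("mass and headspace volume must be positive")
        if np.any(self.co2_pct < 0):
            raise ValidationError("co2_pct must be nonnegative")


@dataclass
class WeightSeries:
    """Berry weight (g) vs storage day, anchored to the day-0 weight w0."""

    day: np.ndarray
    w_g: np.ndarray
    w0_g: float | None = None
    replicate_id: str = ""

    def __post_init__(self):
        self.day = np.asarray(self.day, dtype=float)
        self.w_g = np.asarray(self.w_g, dtype=float)
        if self.day.shape != self.w_g.shape or self.day.ndim != 1:
            raise ValidationError("day and w_g must be matching 1-D arrays")
        if not np.all(np.diff(self.day) > 0):
            raise ValidationError("days must be strictly increasing")
        if np.any(self.w_g < 0):
            raise ValidationError("weights must be nonnegative")
        if self.w0_g is None:
            if self.day[0] != 0:
                raise ValidationError("w0_g required when the series does not start at day 0")
            self.w0_g = float(self.w_g[0])
        if self.w0_g <= 0:
            raise ValidationError("w0_g must be positive")


@dataclass
class PunctureCurve:
    """Force-displacement record of a flat-probe puncture test."""

    displacement_mm: np.ndarray
    force_n: np.ndarray
    probe_diameter_mm: float = 5.0
    max_depth_mm: float = 8.0
    speed_mm_s: float = 1.0
    replicate_id: str = ""

    def __post_init__(self):
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)
        self.force_n = np.asarray(self.force_n, dtype=float)
        if (
            self.displacement_mm.shape != self.force_n.shape
            or self.displacement_mm.ndim != 1
            or self.displacement_mm.size == 0
        ):
            raise ValidationError("displacement and force must be matching nonempty 1-D arrays")
        if np.any(self.displacement_mm < 0) or not np.all(
            np.diff(self.displacement_mm) > 0
        ):
            raise ValidationError("displacement must be nonnegative and increasing")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------
def respiration_rate(
    series: HeadspaceSeries,
    window: tuple[float, float] | None = None,
    *,
    method: str = "endpoints",
) -> float:
    """CO2 production rate in ml CO2 kg^-1 h^-1 over a time window.

    ``endpoints`` (default) uses the difference between the window's first and
    last CO2 readings; ``slope`` regresses CO2 on time across the window,
    which is more robust on noisy series.
    """
    t, c = series.t_h, series.co2_pct
    if window is not None:
        lo, hi = window
        mask = (t >= lo) & (t <= hi)
        t, c = t[mask], c[mask]
    if t.size < 2:
        raise ValidationError("window must span at least 2 samples")
    dt_h = t[-1] - t[0]
    if dt_h <= 0:
        raise ValidationError("zero time span in window")
    if method == "endpoints":
        slope_pct_per_h = (c[-1] - c[0]) / dt_h
    elif method == "slope":
        slope_pct_per_h = float(stats.linregress(t, c).slope)
    else:
        raise ValueError(f"unknown method {method!r}")
    return slope_pct_per_h / 100.0 * series.headspace_ml / series.mass_kg


def weight_loss_fraction(series: WeightSeries, day: float) -> float:
    """Fraction of the day-0 weight lost by ``day``.

    Linear interpolation between sampled days; days outside the sampled range
    raise rather than extrapolate.
    """
    if day < series.day[0] or day > series.day[-1]:
        if day == 0:
            return 0.0
        raise ValidationError(
            f"day {day} outside sampled range [{series.day[0]}, {series.day[-1]}]"
        )
    w = float(np.interp(day, series.day, series.w_g))
    return 1.0 - w / series.w0_g


def max_penetration_force(curve: PunctureCurve) -> float:
    """Maximum force (N) over the first ``max_depth_mm`` of penetration."""
    mask = curve.displacement_mm <= curve.max_depth_mm
    if not mask.any():
        raise ValidationError("no samples within the penetration depth window")
    if curve.displacement_mm[-1] < curve.max_depth_mm:
        warnings.warn(
            f"curve truncated at {curve.displacement_mm[-1]:.2f} mm "
            f"(< {curve.max_depth_mm} mm)",
            stacklevel=2,
        )
    return float(np.max(curve.force_n[mask]))


def firmness_summary(curves: Sequence[PunctureCurve]) -> tuple[float, float, list[float]]:
    """Per-curve maxima, then mean +/- sd across replicates."""
    maxima = [max_penetration_force(c) for c in curves]
    mean = float(np.mean(maxima))
    sd = float(np.std(maxima, ddof=1)) if len(maxima) > 1 else 0.0
    return mean, sd, maxima


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------
def group_compare(
    samples: Mapping[str, Sequence[float]] | pd.DataFrame,
    design: str = "one-way",
    *,
    alpha: float = 0.05,
) -> dict:
    """ANOVA with Tukey HSD pairwise comparisons.

    ``samples`` is either {group label: observations} for a one-way design, or
    a DataFrame with columns ``value``, ``factor_a`` (and ``factor_b`` for the
    two-way design).  Returns a dict with keys ``anova`` (DataFrame: F, p per
    factor) and ``tukey`` (DataFrame of pairwise comparisons with a
    ``reject`` column at the given alpha, over factor_a groups).
    """
    from statsmodels.formula.api import ols
    from statsmodels.stats.anova import anova_lm
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if isinstance(samples, pd.DataFrame):
        df = samples.copy()
    else:
        df = pd.DataFrame(
            [(k, float(v)) for k, vals in samples.items() for v in vals],
            columns=["factor_a", "value"],
        )
    if "factor_a" not in df or "value" not in df:
        raise ValidationError("need 'value' and 'factor_a' columns")
    groups = df.groupby("factor_a")["value"]
    if groups.ngroups < 2 or (groups.count() < 2).any():
        raise ValidationError("need >= 2 groups with >= 2 observations each")

    if design == "one-way":
        model = ols("value ~ C(factor_a)", data=df).fit()
        table = anova_lm(model, typ=2)
        anova = pd.DataFrame(
            {
                "factor": ["factor_a"],
                "F": [float(table.loc["C(factor_a)", "F"])],
                "p": [float(table.loc["C(factor_a)", "PR(>F)"])],
            }
        )
    elif design == "two-way":
        if "factor_b" not in df:
            raise ValidationError("two-way design needs a 'factor_b' column")
        model = ols("value ~ C(factor_a) + C(factor_b)", data=df).fit()
        table = anova_lm(model, typ=2)
        anova = pd.DataFrame(
            {
                "factor": ["factor_a", "factor_b"],
                "F": [
                    float(table.loc["C(factor_a)", "F"]),
                    float(table.loc["C(factor_b)", "F"]),
                ],
                "p": [
                    float(table.loc["C(factor_a)", "PR(>F)"]),
                    float(table.loc["C(factor_b)", "PR(>F)"]),
                ],
            }
        )
    else:
        raise ValueError(f"unknown design {design!r}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance groups trigger RuntimeWarnings
        tukey = pairwise_tukeyhsd(df["value"].to_numpy(), df["factor_a"].to_numpy(), alpha=alpha)
    tukey_df = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return {"anova": anova, "tukey": tukey_df}
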