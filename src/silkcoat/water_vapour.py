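"""Water-vapour transmission rate and permeability from the gravimetric cup
method (ASTM E96 style).

A film is sealed over a cup charged with desiccant (0 % RH inside) and stored
in a desiccator at 75 % RH; moisture crossing the film is weighed as cup mass
gain.  WVTR is the regression slope of weight on time per unit opening area;
permeability normalises by film thickness and the vapour-pressure difference:

    WVTR = slope / A                      [g m^-2 s^-1]
    WVP  = WVTR * d / (S * (RH1 - RH2)/100)   [g m^-1 s^-1 Pa^-1]

with S the saturation vapour pressure of water (2645 Pa at 22 degC), RH1 the
desiccator humidity and RH2 the cup humidity, in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_core import ValidationError

__all__ = [
    "CupExperiment",
    "WvpResult",
    "R2_GATE",
    "fit_wvtr",
    "compute_wvp",
    "analyze_cup",
    "wvp_ratio",
]

# quality gate on the weight-gain regression; series at or below it are flagged
R2_GATE = 0.98

# saturation vapour pressure of water at 22 degC, Pa
S_22C_PA = 2645.0


@dataclass
class CupExperiment:
    """Cup weight record plus the geometry and climate needed for WVP."""

    t_h: np.ndarray
    weight_g: np.ndarray
    area_m2: float
    thickness_m: float
    rh1_pct: float = 75.0
    rh2_pct: float = 0.0
    s_pa: float = S_22C_PA
    temperature_c: float = 22.0
    replicate_id: str = ""

    def __post_init__(self):
        self.t_h = np.asarray(self.t_h, dtype=float)
        self.weight_g = np.asarray(self.weight_g, dtype=float)
        if self.t_h.shape != self.weight_g.shape or self.t_h.ndim != 1:
            raise ValidationError("t_h and weight_g must be matching 1-D arrays")
        if not np.all(np.diff(self.t_h) > 0):
            raise ValidationError("time stamps must be strictly increasing")
        if self.area_m2 <= 0 or self.thickness_m <= 0 or self.s_pa <= 0:
            raise ValidationError("area, thickness and S must be positive")
        if not 0.0 <= self.rh2_pct < self.rh1_pct <= 100.0:
            raise ValidationError("require 0 <= RH2 < RH1 <= 100")


@dataclass(frozen=True)
class WvpResult:
    wvtr_g_m2_s: float
    wvp_g_m_s_pa: float
    r_squared: float
    delta_p_pa: float
    low_r2: bool = False
    direction: str = "gain"  # "gain" (desiccant cup) or "loss" (inverted cup)


def fit_wvtr(cup: CupExperiment) -> tuple[float, float, bool, str]:
    """WVTR from OLS slope of cup weight on time.

    Returns (wvtr in g m^-2 s^-1, r_squared, low_r2 flag, direction).  Weight
    gain is the expected direction; a negative slope (water-loss cup) is
    reported by magnitude with direction "loss".  An r^2 at or below 0.98
    raises the quality flag, mirroring the usual acceptance gate for cup runs.
    """
    if cup.t_h.size < 3:
        raise ValidationError("need at least 3 time points to fit WVTR")
    res = stats.linregress(cup.t_h, cup.weight_g)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
    slope_g_per_h = float(res.slope)
    direction = "loss" if slope_g_per_h < 0 else "gain"
    wvtr = abs(slope_g_per_h) / 3600.0 / cup.area_m2
    return wvtr, r2, r2 <= R2_GATE, direction


def compute_wvp(
    wvtr_g_m2_s: float,
    thickness_m: float,
    s_pa: float,
    rh1_pct: float,
    rh2_pct: float,
    *,
    r_squared: float = 1.0,
    delta_p_pa: float | None = None,
    direction: str = "gain",
) -> WvpResult:
    """Permeability WVP = WVTR * d / delta_p with delta_p = S*(RH1-RH2)/100.

    ``delta_p_pa`` overrides the formula when a fixed driving pressure is to be
    reproduced.
    """
    if rh1_pct <= rh2_pct:
        raise ValidationError("RH1 must exceed RH2")
    if thickness_m <= 0 or s_pa <= 0:
        raise ValidationError("thickness and S must be positive")
    if delta_p_pa is None:
        delta_p_pa = s_pa * (rh1_pct - rh2_pct) / 100.0
    if delta_p_pa <= 0:
        raise ValidationError("driving pressure must be positive")
    wvp = wvtr_g_m2_s * thickness_m / delta_p_pa
    return WvpResult(
        wvtr_g_m2_s=wvtr_g_m2_s,
        wvp_g_m_s_pa=wvp,
        r_squared=r_squared,
        delta_p_pa=delta_p_pa,
        low_r2=r_squared <= R2_GATE,
        direction=direction,
    )


def analyze_cup(cup: CupExperiment, *, delta_p_pa: float | None = None) -> WvpResult:
    """Convenience: regression plus permeability in one step."""
    wvtr, r2, _, direction = fit_wvtr(cup)
    return compute_wvp(
        wvtr,
        cup.thickness_m,
        cup.s_pa,
        cup.rh1_pct,
        cup.rh2_pct,
        r_squared=r2,
        delta_p_pa=delta_p_pa,
        direction=direction,
    )


def wvp_ratio(a: WvpResult | float, b: WvpResult | float) -> float:
    """Fold change a/b between two permeabilities (WvpResult or raw values)."""
    av = a.wvp_g_m_s_pa if isinstance(a, WvpResult) else float(a)
    bv = b.wvp_g_m_s_pa if isinstance(b, WvpResult) else float(b)
    if bv == 0:
        raise ZeroDivisionError("denominator permeability is zero")
    return av / bv
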