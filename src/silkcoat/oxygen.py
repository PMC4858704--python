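"""Effective membrane oxygen diffusivity from two-chamber permeation kinetics.

A film separates a donor chamber held at constant dissolved-oxygen
concentration c_D from a stirred receiving chamber (volume V_R) whose
concentration c_R(t) is tracked with an optical microsensor.  Under
quasi-steady diffusion across a thin film of area A_M and thickness l, and an
additive rig leak ("baseline") proportional to (c* - c_R) with volumetric
factor D_B, the receiving chamber obeys the first-order law

    dc_R/dt = (A_M * D_eM / (l * V_R)) * (c_D - c_R) + (D_B / V_R) * (c* - c_R)

With c* = c_D (saturation equals the donor concentration) this collapses to

    dc_R/dt = alpha * (c_D - c_R),      alpha = k_M * D_eM + D_B / V_R

with k_M = A_M / (l * V_R) the rig's geometric constant.  Integrating,
c_R(t) = c_D - (c_D - c_R0) * exp(-alpha * t): alpha is the slope of
-ln(c_D - c_R) versus time.  A rubber-stopper run (impermeable barrier,
D_eM = 0) measures the leak alone, alpha_rs = D_B / V_R, and the film
diffusivity is recovered by baseline subtraction:

    D_eM = (alpha - alpha_rs) / k_M

alpha is handled in min^-1 (the sensor logs every 10 min); D_eM is reported
in cm^2/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_core import ValidationError, convert

__all__ = [
    "ChamberGeometry",
    "OxygenSeries",
    "DiffusionFit",
    "DiffusivityResult",
    "InsufficientDataError",
    "donor_concentration",
    "model_rhs",
    "solve_closed_form",
    "fit_diffusion_factor",
    "baseline_factor",
    "effective_diffusivity",
    "analyze_film",
]


class InsufficientDataError(ValidationError):
    """Too few usable points to fit the log-linear concentration decay."""


@dataclass(frozen=True)
class ChamberGeometry:
    """Two-chamber rig geometry: opening area (cm^2), film thickness (cm),
    receiving-chamber volume (cm^3)."""

    A_M_cm2: float = 2.75
    l_cm: float = 0.0075  # 75 um, midpoint of the 70-80 um films
    V_R_cm3: float = 100.0

    def __post_init__(self):
        if self.A_M_cm2 <= 0 or self.l_cm <= 0 or self.V_R_cm3 <= 0:
            raise ValidationError("chamber geometry must be strictly positive")

    @property
    def k_M(self) -> float:
        """Geometric constant A_M / (l * V_R), cm^-2."""
        return self.A_M_cm2 / (self.l_cm * self.V_R_cm3)


@dataclass
class OxygenSeries:
    """Receiving-chamber dissolved-oxygen record.

    t in minutes (strictly increasing), c_R in mg/L, constant donor
    concentration c_D in mg/L; c_star defaults to c_D (saturation).
    """

    t_min: np.ndarray
    c_R: np.ndarray
    c_D: float
    c_star: float | None = None
    replicate_id: str = ""

    def __post_init__(self):
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.c_R = np.asarray(self.c_R, dtype=float)
        if self.t_min.shape != self.c_R.shape or self.t_min.ndim != 1:
            raise ValidationError("t_min and c_R must be matching 1-D arrays")
        if not np.all(np.diff(self.t_min) > 0):
            raise ValidationError("time stamps must be strictly increasing")
        if self.c_D <= 0:
            raise ValidationError("c_D must be positive")
        if np.any(self.c_R < 0):
            raise ValidationError("c_R must be nonnegative")
        if self.c_star is None:
            self.c_star = self.c_D


@dataclass(frozen=True)
class DiffusionFit:
    """Log-linear fit of ln(c_D - c_R) on t: alpha = -slope (min^-1)."""

    alpha_per_min: float
    intercept: float
    r_squared: float
    n_points_used: int
    n_points_excluded: int = 0


@dataclass(frozen=True)
class DiffusivityResult:
    """Baseline-corrected effective film diffusivity with replicate stats."""

    D_eM_cm2_per_s: float
    D_B_cm3_per_min: float
    alpha_per_min: float
    alpha_rs_per_min: float
    k_M_per_cm2: float
    alpha_replicates: tuple[float, ...] = ()
    alpha_mean: float = float("nan")
    alpha_sd: float = float("nan")
    below_baseline: bool = False
    flags: tuple[str, ...] = ()


def donor_concentration(c_initial: float, c_final: float) -> float:
    """Working donor concentration: the average of the initial and final
    donor-chamber readings (the donor is nominally constant; averaging absorbs
    sensor drift over a run)."""
    if c_initial <= 0 or c_final <= 0:
        raise ValidationError("donor readings must be positive")
    return 0.5 * (c_initial + c_final)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------
def model_rhs(
    c_R: float | np.ndarray,
    c_D: float,
    c_star: float,
    D_eM_cm2_per_min: float,
    D_B_cm3_per_min: float,
    geometry: ChamberGeometry,
):
    """Rate of change of the receiving-chamber concentration, mg L^-1 min^-1.

    Membrane term (A_M*D_eM/(l*V_R))*(c_D - c_R) plus leak term
    (D_B/V_R)*(c_star - c_R).
    """
    membrane = geometry.k_M * D_eM_cm2_per_min * (c_D - np.asarray(c_R, dtype=float))
    leak = (D_B_cm3_per_min / geometry.V_R_cm3) * (c_star - np.asarray(c_R, dtype=float))
    return membrane + leak


def solve_closed_form(c_R0: float, c_D: float, alpha_per_min: float, t_min):
    """c_R(t) = c_D - (c_D - c_R0) * exp(-alpha t) for alpha >= 0."""
    if alpha_per_min < 0:
        raise ValidationError("alpha must be nonnegative")
    t = np.asarray(t_min, dtype=float)
    return c_D - (c_D - c_R0) * np.exp(-alpha_per_min * t)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------
def fit_diffusion_factor(series: OxygenSeries) -> DiffusionFit:
    """Estimate the diffusion factor alpha by OLS of ln(c_D - c_R) on t.

    Points at or above the donor concentration (sensor overshoot) are excluded
    and counted rather than raised on; at least 4 usable points are required.
    """
    deficit = series.c_D - series.c_R
    usable = deficit > 0
    n_excl = int(np.sum(~usable))
    t = series.t_min[usable]
    if t.size < 4:
        raise InsufficientDataError(
            f"need >= 4 points with c_R < c_D, have {t.size} "
            f"({n_excl} excluded at/above donor concentration)"
        )
    if np.ptp(t) == 0:
        raise ValidationError("zero time variance among usable points")
    logdef = np.log(deficit[usable])
    res = stats.linregress(t, logdef)
    # a perfectly flat series gives slope 0 and undefined r; report r^2 = 0
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
    alpha = -float(res.slope)
    if abs(alpha) < 1e-15:
        alpha = 0.0
    return DiffusionFit(
        alpha_per_min=alpha,
        intercept=float(res.intercept),
        r_squared=r2,
        n_points_used=int(t.size),
        n_points_excluded=n_excl,
    )


def baseline_factor(
    stopper_series: OxygenSeries, geometry: ChamberGeometry
) -> tuple[float, float]:
    """Leak rate from a rubber-stopper run: alpha_rs (min^-1) and
    D_B = alpha_rs * V_R (cm^3/min)."""
    fit = fit_diffusion_factor(stopper_series)
    alpha_rs = fit.alpha_per_min
    return alpha_rs, alpha_rs * geometry.V_R_cm3


def effective_diffusivity(
    alpha_per_min: float,
    alpha_rs_per_min: float,
    geometry: ChamberGeometry,
) -> DiffusivityResult:
    """Baseline-corrected film diffusivity D_eM = (alpha - alpha_rs)/k_M.

    Negative differences (leak exceeding the film run, possible at very low
    permeability) are clipped to zero and flagged rather than reported as a
    negative diffusivity.
    """
    if not (np.isfinite(alpha_per_min) and np.isfinite(alpha_rs_per_min)):
        raise ValidationError("alpha and alpha_rs must be finite")
    diff = alpha_per_min - alpha_rs_per_min
    below = diff < 0
    D_eM_cm2_per_min = max(diff, 0.0) / geometry.k_M
    flags = ("below_baseline",) if below else ()
    return DiffusivityResult(
        D_eM_cm2_per_s=convert(D_eM_cm2_per_min, "cm2/min", "cm2/s"),
        D_B_cm3_per_min=alpha_rs_per_min * geometry.V_R_cm3,
        alpha_per_min=alpha_per_min,
        alpha_rs_per_min=alpha_rs_per_min,
        k_M_per_cm2=geometry.k_M,
        below_baseline=below,
        flags=flags,
    )


def analyze_film(
    replicate_series: list[OxygenSeries],
    stopper_series: OxygenSeries,
    geometry: ChamberGeometry,
) -> DiffusivityResult:
    """Full film analysis: per-replicate alpha, mean +/- sd, baseline-corrected
    D_eM from the mean alpha.

    Replicates whose fit fails (too few usable points) are dropped with a
    warning; at least one must survive.
    """
    alphas: list[float] = []
    flags: list[str] = []
    for series in replicate_series:
        try:
            alphas.append(fit_diffusion_factor(series).alpha_per_min)
        except InsufficientDataError as exc:
            warnings.warn(
                f"replicate {series.replicate_id!r} unusable: {exc}", stacklevel=2
            )
            flags.append(f"replicate_dropped:{series.replicate_id}")
    if not alphas:
        raise InsufficientDataError("no usable replicate series")
    alpha_mean = float(np.mean(alphas))
    alpha_sd = float(np.std(alphas, ddof=1)) if len(alphas) > 1 else 0.0
    alpha_rs, _ = baseline_factor(stopper_series, geometry)
    base = effective_diffusivity(alpha_mean, alpha_rs, geometry)
    return DiffusivityResult(
        D_eM_cm2_per_s=base.D_eM_cm2_per_s,
        D_B_cm3_per_min=base.D_B_cm3_per_min,
        alpha_per_min=alpha_mean,
        alpha_rs_per_min=alpha_rs,
        k_M_per_cm2=geometry.k_M,
        alpha_replicates=tuple(alphas),
        alpha_mean=alpha_mean,
        alpha_sd=alpha_sd,
        below_baseline=base.below_baseline,
        flags=tuple(flags) + base.flags,
    )
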