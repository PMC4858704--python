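"""Synthetic instrument-output generators with known ground truth.

Every estimator in the pipeline is validated by parameter recovery: these
generators produce the five raw instrument records (receiving-chamber oxygen,
cup weight, Amide III spectrum, jar headspace CO2, berry weight, puncture
force) from stated true parameters plus seeded noise, so a fit can be checked
against the truth it was generated from.

All generators are pure functions of their arguments and seed: the same call
returns a bit-identical record.  Noiseless output satisfies the corresponding
estimator's model exactly.

Noise conventions (chosen to mimic each instrument):
  * oxygen optode: multiplicative, sd as a fraction of the current reading
    (optical sensors have roughly constant relative error);
  * balance (cup, berries): additive, sd in grams;
  * FTIR: additive, sd as a fraction of the peak absorbance;
  * CO2 probe: additive, sd in percentage points;
  * load cell: additive, sd in newtons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ftir import BETA_WINDOW, Spectrum
from .io_core import CoatingCondition, TimeSeries, ValidationError
from .oxygen import ChamberGeometry, OxygenSeries, solve_closed_form
from .water_vapour import CupExperiment, S_22C_PA

__all__ = [
    "ScenarioSpec",
    "DEFAULT_GEOMETRY",
    "DONOR_O2_MG_L",
    "BETA_PCT_BY_ANNEALING_H",
    "TABLE2_WVP",
    "gen_oxygen_experiment",
    "gen_stopper_experiment",
    "gen_cup_series",
    "default_amide3_bands",
    "gen_amide3_spectrum",
    "gen_dehydration_series",
    "default_headspace_schedule",
    "gen_headspace_series",
    "gen_puncture_curve",
    "oxygen_schedule",
    "table1_scenarios",
]

# rig defaults: opening 2.75 cm^2, film 75 um (midpoint of the 70-80 um films);
# the receiving volume is not a stated rig property and is configurable.
DEFAULT_GEOMETRY = ChamberGeometry(A_M_cm2=2.75, l_cm=0.0075, V_R_cm3=100.0)

# donor-chamber dissolved O2, mg/L: air-saturated water at room temperature.
DONOR_O2_MG_L = 8.0

# water-annealing time (h) -> relative beta-sheet content (%) of the coating
BETA_PCT_BY_ANNEALING_H = {0: 23.0, 1: 36.0, 6: 48.0, 12: 58.0}

# measured film permeabilities (g m^-1 s^-1 Pa^-1) by beta-sheet content;
# used as scenario truths for the annealed films
TABLE2_WVP = {36.0: 7.93e-9, 48.0: 5.37e-10, 58.0: 6.49e-11}

# cup geometry: circular opening of 14 mm diameter
CUP_AREA_M2 = float(np.pi * (0.014 / 2) ** 2)


@dataclass(frozen=True)
class ScenarioSpec:
    """Ground truth for one coating condition across all five instruments."""

    condition: CoatingCondition
    true_D_eM_cm2_s: float
    true_D_B_cm3_min: float
    true_wvtr_g_m2_s: float
    true_beta_fraction: float
    respiration_ml_kg_h: float
    dehydration_k_per_day: float
    seed: int
    oxygen_noise_sd: float = 0.01  # fraction of reading
    cup_noise_sd_g: float = 1e-4
    spectrum_noise_sd: float = 0.01  # fraction of peak absorbance
    headspace_noise_sd_pct: float = 0.02
    weight_noise_sd_g: float = 0.05
    force_noise_sd_n: float = 0.05
    peak_force_n: float = 3.0
    peak_depth_mm: float = 6.0

    def __post_init__(self):
        for name in (
            "true_D_eM_cm2_s",
            "true_D_B_cm3_min",
            "true_wvtr_g_m2_s",
            "respiration_ml_kg_h",
            "dehydration_k_per_day",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")
        if not 0.0 <= self.true_beta_fraction <= 1.0:
            raise ValidationError("true_beta_fraction must be in [0, 1]")
        for name in (
            "oxygen_noise_sd",
            "cup_noise_sd_g",
            "spectrum_noise_sd",
            "headspace_noise_sd_pct",
            "weight_noise_sd_g",
            "force_noise_sd_n",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")


# ---------------------------------------------------------------------------
# Oxygen permeation
# ---------------------------------------------------------------------------
def oxygen_schedule(duration_min: float = 360.0, interval_min: float = 10.0) -> np.ndarray:
    """Default optode schedule: one reading every 10 minutes for 6 hours."""
    return np.arange(0.0, duration_min + 0.5 * interval_min, interval_min)


def _oxygen_alpha(spec: ScenarioSpec, geometry: ChamberGeometry, membrane: bool) -> float:
    d_em_cm2_min = spec.true_D_eM_cm2_s * 60.0 if membrane else 0.0
    return geometry.k_M * d_em_cm2_min + spec.true_D_B_cm3_min / geometry.V_R_cm3


def _gen_oxygen(
    spec: ScenarioSpec,
    geometry: ChamberGeometry,
    schedule: np.ndarray,
    membrane: bool,
    c_D: float,
    c_R0: float,
    replicate_id: str,
    seed_offset: int,
) -> OxygenSeries:
    t = np.asarray(schedule, dtype=float)
    if t.size == 0:
        raise ValidationError("schedule must be nonempty")
    alpha = _oxygen_alpha(spec, geometry, membrane)
    c = solve_closed_form(c_R0, c_D, alpha, t)
    if spec.oxygen_noise_sd > 0:
        rng = np.random.default_rng((spec.seed, seed_offset))
        c = c * (1.0 + rng.normal(0.0, spec.oxygen_noise_sd, size=t.size))
        c = np.clip(c, 0.0, None)
    return OxygenSeries(t, c, c_D=c_D, replicate_id=replicate_id)


def gen_oxygen_experiment(
    spec: ScenarioSpec,
    geometry: ChamberGeometry = DEFAULT_GEOMETRY,
    schedule: np.ndarray | None = None,
    *,
    c_D: float = DONOR_O2_MG_L,
    c_R0: float = 0.0,
    replicate_id: str = "r1",
    seed_offset: int = 0,
) -> OxygenSeries:
    """Receiving-chamber O2 trace for a film with the spec's true D_eM and D_B."""
    if schedule is None:
        schedule = oxygen_schedule()
    return _gen_oxygen(spec, geometry, schedule, True, c_D, c_R0, replicate_id, seed_offset)


def gen_stopper_experiment(
    spec: ScenarioSpec,
    geometry: ChamberGeometry = DEFAULT_GEOMETRY,
    schedule: np.ndarray | None = None,
    *,
    c_D: float = DONOR_O2_MG_L,
    c_R0: float = 0.0,
    replicate_id: str = "stopper",
    seed_offset: int = 1000,
) -> OxygenSeries:
    """Rubber-stopper (impermeable barrier) trace: rig leak only, D_eM = 0."""
    if schedule is None:
        schedule = oxygen_schedule()
    return _gen_oxygen(spec, geometry, schedule, False, c_D, c_R0, replicate_id, seed_offset)


# ---------------------------------------------------------------------------
# Cup method
# ---------------------------------------------------------------------------
def gen_cup_series(
    true_wvtr_g_m2_s: float,
    area_m2: float = CUP_AREA_M2,
    schedule_h: np.ndarray | None = None,
    noise_sd_g: float = 1e-4,
    seed: int = 0,
    *,
    w0_g: float = 50.0,
    thickness_m: float = 75e-6,
    rh1_pct: float = 75.0,
    rh2_pct: float = 0.0,
    s_pa: float = S_22C_PA,
    replicate_id: str = "cup1",
) -> CupExperiment:
    """Desiccant-cup weight record: linear gain true_wvtr * area per second."""
    if true_wvtr_g_m2_s < 0 or noise_sd_g < 0:
        raise ValidationError("wvtr and noise sd must be nonnegative")
    if schedule_h is None:
        schedule_h = np.arange(0.0, 48.5, 1.0)  # hourly weighings over 2 days
    t = np.asarray(schedule_h, dtype=float)
    weight = w0_g + true_wvtr_g_m2_s * area_m2 * t * 3600.0
    if noise_sd_g > 0:
        rng = np.random.default_rng((seed, 2000))
        weight = weight + rng.normal(0.0, noise_sd_g, size=t.size)
    return CupExperiment(
        t, weight, area_m2=area_m2, thickness_m=thickness_m,
        rh1_pct=rh1_pct, rh2_pct=rh2_pct, s_pa=s_pa, replicate_id=replicate_id,
    )


# ---------------------------------------------------------------------------
# Amide III spectrum
# ---------------------------------------------------------------------------
def default_amide3_bands(
    beta_fraction: float,
    beta_window: tuple[float, float] = BETA_WINDOW,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Band layout realising a given relative beta-sheet area fraction.

    Twelve components evenly spaced on 1212-1338 cm^-1, sigma 4 cm^-1
    (FWHM ~9 cm^-1, typical of deconvolved Amide III components).  The grid is inset
    from the 1200-1350 cm^-1 region so the band envelope decays towards the
    region edges, as real Amide III spectra do (the deconvolution's
    endpoint-anchored baseline correction presumes near-zero edge signal).
    The beta fraction is split evenly over the bands whose centres fall
    inside the beta window, the rest evenly over the others.
    Returns (centers, sigmas, areas, is_beta).
    """
    if not 0.0 <= beta_fraction <= 1.0:
        raise ValidationError("beta_fraction must be in [0, 1]")
    centers = np.linspace(1212.0, 1338.0, 12)
    sigmas = np.full(12, 4.0)
    is_beta = (centers >= beta_window[0]) & (centers <= beta_window[1])
    n_beta = int(is_beta.sum())
    areas = np.empty(12)
    areas[is_beta] = beta_fraction / n_beta
    areas[~is_beta] = (1.0 - beta_fraction) / (12 - n_beta)
    return centers, sigmas, areas, is_beta


def gen_amide3_spectrum(
    band_centers: np.ndarray,
    widths: np.ndarray,
    areas: np.ndarray,
    noise_sd: float = 0.01,
    seed: int = 0,
    *,
    baseline: tuple[float, float] = (0.0, 0.0),  # (offset, slope per cm^-1)
    grid: np.ndarray | None = None,
    scale: float = 1.0,
) -> Spectrum:
    """Amide III trace: sum of Gaussians + linear baseline + additive noise.

    ``noise_sd`` is relative to the peak of the noiseless band sum.  Centers
    must lie inside the Amide III region; areas must be nonnegative.
    """
    centers = np.asarray(band_centers, dtype=float)
    sigmas = np.asarray(widths, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if centers.size != 12:
        raise ValidationError("expected 12 band centers")
    if np.any(centers < 1200.0) or np.any(centers > 1350.0):
        raise ValidationError("band centers must lie in 1200-1350 cm^-1")
    if np.any(areas < 0) or np.any(sigmas <= 0):
        raise ValidationError("areas must be >= 0 and widths > 0")
    if grid is None:
        grid = np.arange(1200.0, 1350.0 + 0.25, 0.5)
    nu = np.asarray(grid, dtype=float)
    amp = areas / (sigmas * np.sqrt(2.0 * np.pi))
    signal = np.sum(
        amp[:, None] * np.exp(-0.5 * ((nu[None, :] - centers[:, None]) / sigmas[:, None]) ** 2),
        axis=0,
    )
    absorb = scale * signal + baseline[0] + baseline[1] * (nu - nu[0])
    if noise_sd > 0:
        rng = np.random.default_rng((seed, 3000))
        absorb = absorb + rng.normal(0.0, noise_sd * scale * signal.max(), size=nu.size)
    return Spectrum(nu, absorb)


# ---------------------------------------------------------------------------
# Dehydration
# ---------------------------------------------------------------------------
def gen_dehydration_series(
    w0_g: float,
    k_per_day: float,
    w_eq_fraction: float = 0.25,
    days: np.ndarray | None = None,
    noise_sd_g: float = 0.05,
    seed: int = 0,
    *,
    replicate_id: str = "berry1",
) -> TimeSeries:
    """Berry weight: first-order approach to an equilibrium (dry-matter) weight,
    w(t) = w_eq + (w0 - w_eq) exp(-k t), w_eq = w_eq_fraction * w0."""
    if w0_g <= 0 or k_per_day < 0 or not 0.0 <= w_eq_fraction <= 1.0:
        raise ValidationError("invalid dehydration parameters")
    if days is None:
        days = np.array([0.0, 1.0, 3.0, 5.0, 7.0, 14.0])
    t = np.asarray(days, dtype=float)
    w_eq = w_eq_fraction * w0_g
    w = w_eq + (w0_g - w_eq) * np.exp(-k_per_day * t)
    if noise_sd_g > 0:
        rng = np.random.default_rng((seed, 4000))
        w = np.clip(w + rng.normal(0.0, noise_sd_g, size=t.size), 0.0, None)
    return TimeSeries(t, w, t_unit="day", y_unit="g", replicate_id=replicate_id)


# ---------------------------------------------------------------------------
# Respiration headspace
# ---------------------------------------------------------------------------
def default_headspace_schedule() -> np.ndarray:
    """Jar sampling times (h): every 30 min for the first 5 h, every 90 min to
    the 12th hour, every 180 min for the remaining 24 h (36 h total)."""
    times = [0.0]
    t = 0.0
    while t < 5.0 - 1e-9:
        t += 0.5
        times.append(t)
    while t < 12.0 - 1e-9:
        t += 1.5
        times.append(t)
    end = t + 24.0
    while t < end - 1e-9:
        t += 3.0
        times.append(t)
    return np.array(times)


def gen_headspace_series(
    rate_ml_kg_h: float,
    mass_kg: float = 0.1,
    headspace_ml: float = 900.0,
    schedule_h: np.ndarray | None = None,
    noise_sd_pct: float = 0.02,
    seed: int = 0,
    *,
    co2_0_pct: float = 0.04,
    replicate_id: str = "jar1",
):
    """Closed-jar CO2 accumulation: %CO2(t) = %CO2(0) + 100 * R m t / V + noise."""
    from .postharvest import HeadspaceSeries

    if rate_ml_kg_h < 0 or mass_kg <= 0 or headspace_ml <= 0 or noise_sd_pct < 0:
        raise ValidationError("invalid headspace parameters")
    if schedule_h is None:
        schedule_h = default_headspace_schedule()
    t = np.asarray(schedule_h, dtype=float)
    co2 = co2_0_pct + 100.0 * rate_ml_kg_h * mass_kg * t / headspace_ml
    if noise_sd_pct > 0:
        rng = np.random.default_rng((seed, 5000))
        co2 = np.clip(co2 + rng.normal(0.0, noise_sd_pct, size=t.size), 0.0, None)
    return HeadspaceSeries(t, co2, mass_kg=mass_kg, headspace_ml=headspace_ml,
                           replicate_id=replicate_id)


# ---------------------------------------------------------------------------
# Puncture test
# ---------------------------------------------------------------------------
def gen_puncture_curve(
    peak_force_n: float,
    peak_depth_mm: float = 6.0,
    length_mm: float = 8.0,
    noise_sd_n: float = 0.05,
    seed: int = 0,
    *,
    step_mm: float = 0.1,
    replicate_id: str = "fruit1",
):
    """Smooth unimodal force-displacement curve peaking at the stated point.

    Shape: F(x) = F_p * ((x/x_p) * exp(1 - x/x_p))^2 — zero at contact, single
    maximum F_p at x_p, decaying beyond (tissue rupture).  Sampled every
    ``step_mm`` (1 mm/s crosshead, 10 Hz logging).
    """
    from .postharvest import PunctureCurve

    if peak_force_n < 0 or peak_depth_mm <= 0 or length_mm <= 0 or noise_sd_n < 0:
        raise ValidationError("invalid puncture parameters")
    x = np.arange(0.0, length_mm + 0.5 * step_mm, step_mm)
    rel = x / peak_depth_mm
    force = peak_force_n * (rel * np.exp(1.0 - rel)) ** 2
    if noise_sd_n > 0:
        rng = np.random.default_rng((seed, 6000))
        force = np.clip(force + rng.normal(0.0, noise_sd_n, size=x.size), 0.0, None)
    return PunctureCurve(x, force, replicate_id=replicate_id)


# ---------------------------------------------------------------------------
# Scenario set emulating the four water-annealing conditions
# ---------------------------------------------------------------------------
def table1_scenarios(
    seed: int = 0,
    *,
    d_em_top_cm2_s: float = 1e-5,
    d_em_ratio: float = 0.01,
    d_b_cm3_min: float = 0.02,
    noiseless: bool = False,
) -> list[ScenarioSpec]:
    """One ScenarioSpec per water-annealing condition (0, 1, 6, 12 h).

    Beta-sheet content follows the measured annealing map {23, 36, 48, 58}%.
    True oxygen diffusivity decreases geometrically with beta content, spanning
    ``d_em_ratio`` (default 0.01: the reported two-orders-of-magnitude drop;
    the alternative 50-fold reading corresponds to d_em_ratio=0.02) from the
    untreated to the 12 h film.  True WVP uses the measured film values for
    the annealed conditions and a log-linear extrapolation for the untreated
    film; true respiration, dehydration and firmness decline/improve with
    beta content at magnitudes typical of strawberries at 22 degC.
    """
    betas = sorted(BETA_PCT_BY_ANNEALING_H.items())  # [(0,23), (1,36), ...]
    beta_lo, beta_hi = betas[0][1], betas[-1][1]
    # WVP truths (g m^-1 s^-1 Pa^-1); untreated film extrapolated log-linearly
    # from the 36->48% trend
    wvp_truth = dict(TABLE2_WVP)
    slope = (np.log(TABLE2_WVP[48.0]) - np.log(TABLE2_WVP[36.0])) / (48.0 - 36.0)
    wvp_truth[beta_lo] = float(np.exp(np.log(TABLE2_WVP[36.0]) + slope * (beta_lo - 36.0)))
    delta_p = S_22C_PA * 0.75
    thickness_m = 75e-6
    respiration = {23.0: 20.0, 36.0: 16.0, 48.0: 12.0, 58.0: 9.0}
    dehydration_k = {23.0: 0.15, 36.0: 0.10, 48.0: 0.085, 58.0: 0.075}
    peak_force = {23.0: 2.2, 36.0: 2.6, 48.0: 3.0, 58.0: 3.4}
    specs = []
    for i, (hours, beta) in enumerate(betas):
        frac = (beta - beta_lo) / (beta_hi - beta_lo)
        spec = ScenarioSpec(
            condition=CoatingCondition(
                dip_steps=4, annealing_hours=hours, beta_sheet_pct=beta,
                thickness_um=75.0,
            ),
            true_D_eM_cm2_s=d_em_top_cm2_s * d_em_ratio**frac,
            true_D_B_cm3_min=d_b_cm3_min,
            true_wvtr_g_m2_s=wvp_truth[beta] * delta_p / thickness_m,
            true_beta_fraction=beta / 100.0,
            respiration_ml_kg_h=respiration[beta],
            dehydration_k_per_day=dehydration_k[beta],
            peak_force_n=peak_force[beta],
            seed=seed * 100 + i,
        )
        if noiseless:
            spec = replace(
                spec,
                oxygen_noise_sd=0.0, cup_noise_sd_g=0.0, spectrum_noise_sd=0.0,
                headspace_noise_sd_pct=0.0, weight_noise_sd_g=0.0, force_noise_sd_n=0.0,
            )
        specs.append(spec)
    return specs
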