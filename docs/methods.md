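# Methods

This note documents the models behind each estimator, the defaults and the
assumptions they encode, what the synthetic-data generators do and do not
emulate, and the numerical choices that matter.

## Oxygen diffusivity (two-chamber permeation)

**Model.** A film of area *A_M* (cm²) and thickness *l* (cm) separates a
donor chamber at constant dissolved-oxygen concentration *c_D* (mg/L) from a
stirred receiving chamber of volume *V_R* (cm³). Assumptions: well-mixed
fluid on both sides, no oxygen consumption, a linear concentration profile
across the film, and instantaneous quasi-steady state. The film flux is
*j_M = (D_e,M / l)(c_D − c_R)*; the rig additionally leaks oxygen at a rate
proportional to the saturation deficit, *Q_B = D_B (c\* − c_R)*, with *D_B*
a volumetric factor (cm³/min) and *c\** the saturation concentration, taken
equal to *c_D*. Together:

    dc_R/dt = α (c_D − c_R),   α = k_M D_e,M + D_B / V_R,   k_M = A_M / (l V_R)

whose solution is *c_R(t) = c_D − (c_D − c_R0) e^{−αt}*. *α* (min⁻¹) is
estimated by ordinary least squares of ln(c_D − c_R) on *t*; a run with an
impermeable rubber stopper in place of the film gives the leak alone,
*α_rs = D_B/V_R*, and

    D_e,M = (α − α_rs) / k_M,

reported in cm²/s.

**Numerical choices.** Readings at or above *c_D* (sensor overshoot) are
excluded from the log fit and counted, not raised on; fewer than 4 usable
points is an error. A negative baseline-corrected difference is clipped to
zero with a `below_baseline` flag — the rig cannot resolve a film tighter
than its own leak, and a negative diffusivity is unphysical. Replicate runs
(3 by default) are fitted separately; the condition-level *D_e,M* comes from
the mean *α*, with the replicate spread reported as mean ± sd. The working
donor concentration can be formed as the average of the initial and final
donor readings (`donor_concentration`), absorbing slow sensor drift.

**Defaults.** *A_M* = 2.75 cm² (the rig opening); *l* = 75 μm, the midpoint
of the 70–80 μm films; sampling every 10 min for 6 h. *V_R* = 100 cm³ and
*c_D* = 8 mg/L (air-saturated water at room temperature) are **assumptions**
— neither is a measured rig property here — and both are configurable.
Because *D_e,M* divides by *k_M ∝ 1/V_R* while *α_rs V_R = D_B*, the
recovered diffusivity is invariant to the assumed *V_R* so long as the same
value is used in simulation and analysis; only the physical interpretation
of *D_B* depends on it.

## Water-vapour permeability (cup method)

The cup holds desiccant (RH₂ = 0 %) and sits in a desiccator at RH₁ = 75 %;
moisture crossing the sealed film accumulates as weight gain. WVTR is the
OLS slope of weight (g) on time (h), divided by 3600 and the opening area
(default: Ø 14 mm, 1.5394·10⁻⁴ m²), in g m⁻² s⁻¹. Permeability:

    WVP = WVTR · d / Δp,   Δp = S · (RH₁ − RH₂)/100

with *S* = 2645 Pa at 22 °C, so Δp = 1983.75 Pa by default. A fit with
r² ≤ 0.98 raises a quality flag (the usual gate for accepting a cup run).
Inverted (weight-loss) cups are handled by magnitude with a direction flag.

Note: a driving pressure of 1753.55 Pa is sometimes quoted for the 75 %-RH
configuration; that equals 0.75 × 2338 Pa, i.e. the saturation pressure near
20 °C rather than 22 °C. The formula value is the default and a
`delta_p_pa` override exists to reproduce a fixed printed pressure.

## Beta-sheet content (Amide III deconvolution)

The Amide III region (1200–1350 cm⁻¹) is used because it is sensitive to
protein secondary structure and nearly insensitive to water. Processing:

1. slice the spectrum to [1200, 1350] cm⁻¹ (inclusive);
2. subtract a linear baseline anchored at the two endpoint absorbances
   (chosen over rubber-band correction for determinism), clip negative
   residuals to zero (counted), scale to unit area;
3. fit 12 Gaussian components by bounded trust-region least squares:
   centres start on an even grid inset 5 cm⁻¹ from the region edges and may
   move ±8 cm⁻¹; widths are bounded to [2, 25] cm⁻¹; amplitudes are
   nonnegative. Amplitude initialisation solves a nonnegative linear
   least-squares problem against the fixed-centre design matrix, and the
   solver restarts deterministically over initial widths {4, 8, 14} cm⁻¹,
   stopping early once the residual reaches the spectrum's own noise floor
   (estimated from first differences). The fit is deterministic given the
   initial centres; non-convergence is reported via a flag, never raised.
4. bands whose fitted centre falls in the beta-sheet window — default
   1216–1250 cm⁻¹, a conventional Amide III assignment, configurable —
   are summed: beta % = 100 · Σ(beta areas)/Σ(all areas).

Because the spectrum is area-normalised, the result is invariant to overall
intensity scaling. The exact band positions and assignments used by any
particular instrument workflow are not knowable from the summary
percentages alone; the window is therefore an explicit parameter, and the
annealing-series percentages {23, 36, 48, 58} are used as *scenario truths*
for recovery testing, not as reproducible outputs on real spectra.

**Known bias.** The endpoint-anchored baseline removes whatever band-tail
signal reaches the region edges. With the default synthetic layout the
effect is a deterministic bias below 0.5 percentage points; on spectra whose
components hug the region edges it grows quickly. A noiseless end-to-end
run therefore recovers beta % to ~0.3 points, not to machine precision.

## Postharvest metrics

- **Respiration**: R = (ΔCO₂/100 · V)/(m · Δt) in ml CO₂ kg⁻¹ h⁻¹, with
  ΔCO₂ the rise in headspace CO₂ (percentage points) between the first and
  last sample of the chosen window, *V* the free jar volume (ml, a required
  user input — jar volume minus fruit), *m* the fruit mass (kg). A
  regression-slope variant (`method="slope"`) is offered for noisy series.
- **Dehydration**: weight-loss fraction 1 − w(day)/w₀ with linear
  interpolation between sampled days; extrapolation is refused.
- **Firmness**: maximum force over the first 8 mm of a flat-probe (Ø 5 mm,
  1 mm/s) puncture curve; truncated curves warn. Replicates are aggregated
  as per-curve maxima, then mean ± sd.
- **Group comparison**: one-way ANOVA (default) or additive two-way ANOVA,
  with Tukey HSD pairwise testing at α = 0.05, via statsmodels. Both
  designs exist because storage-time × coating layouts are naturally
  two-factor, while single-time-point comparisons are one-way.

## Synthetic data: the stated world

Each generator is a pure function of its parameters and an explicit seed
(bit-identical on repeat); noiseless output satisfies the corresponding
estimator's model exactly. Noise is additive i.i.d. Gaussian per channel,
matched to the instrument: relative (1 % of reading) for the optical oxygen
sensor, absolute for the balance (0.1 mg), CO₂ probe (0.02 %-points) and
load cell (0.05 N), and relative to peak absorbance (1 %) for FTIR.

The four-condition scenario maps water-annealing time {0, 1, 6, 12} h to
beta-sheet {23, 36, 48, 58} %. True oxygen diffusivity decreases
geometrically across the series spanning a factor of 0.01 (two orders of
magnitude; the alternative 50-fold reading is available as
`d_em_ratio=0.02`), from 10⁻⁵ cm²/s for the untreated film. True WVP uses
the measured film values {7.93·10⁻⁹, 5.37·10⁻¹⁰, 6.49·10⁻¹¹} g m⁻¹ s⁻¹ Pa⁻¹
for the annealed conditions and a log-linear extrapolation (1.47·10⁻⁷) for
the untreated film. Respiration {20, 16, 12, 9} ml kg⁻¹ h⁻¹, dehydration
rate constants {0.15, 0.10, 0.085, 0.075} day⁻¹ toward an equilibrium at
25 % of the initial weight (the untreated-control rate 0.19 day⁻¹ would
reproduce the ~70 % two-week loss of uncoated fruit), and puncture peaks
{2.2, 2.6, 3.0, 3.4} N are set at magnitudes typical of strawberries at
22 °C, declining/improving with beta content. The baseline leak
*D_B* = 0.02 cm³/min is a fixed rig property across conditions.

The dehydration curve's first-order form and the puncture curve's unimodal
shape *F(x) = F_p (x/x_p · e^{1−x/x_p})²* are modelling choices — the real
measurements are empirical curves. The generators emulate sampling
schedules, magnitudes and sensor noise; they do **not** emulate microbial
decay, ethylene signalling, temperature drift, film defects or
between-fruit biological variability. A green recovery test therefore
establishes that each estimator inverts its own measurement model at
realistic noise — not that the model captures every feature of real fruit.

The jar-sampling schedule enumerates the stated protocol literally: 30-min
steps to 5 h, then 90-min steps (reaching 12.5 h), then 180-min steps for a
further 24 h — 23 samples after t = 0 over 36.5 h.

## Limitations

- Single-layer films, concentration-independent diffusivity, no oxygen
  consumption in the receiving chamber.
- No temperature model for saturation vapour pressure; *S* is a constant.
- No absolute crystallinity: the FTIR result is a relative area fraction
  under a fixed assignment window.
- The baseline-corrected diffusivity cannot distinguish a very tight film
  from the rig leak; such runs are flagged rather than resolved.
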