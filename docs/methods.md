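# Methods

This note documents the models and procedures implemented in `drydown`,
the defaults chosen where the underlying experimental protocol leaves the
analysis open, and what the synthetic-data tests do and do not demonstrate.

## The analysis

The package reconstructs a drydown–rewatering analysis chain for potted
trees instrumented at 15-min resolution (meteorology, heat-pulse sap flow,
stem water content) with intensive sampling days for leaf water potential,
soil moisture and stable water isotopes. The chain is:

1. **Sensor cleaning** (`sensor_processing`). Fixed order: large negative
   heat-velocity excursions are *removed* (sensor malfunction, not
   interpolated); heat velocity is converted to sap flux by the tree's
   sapwood area; a Hampel filter replaces spikes with the rolling median;
   the series baseline is shifted so its minimum usable value — assumed to
   be a no-transpiration period — is zero. Hampel decisions are invariant
   to the baseline shift (medians and MADs are translation-equivariant),
   so the relative order of the last two steps cannot change which points
   are flagged; the implemented order applies the filter to converted
   fluxes.
2. **Daily summarisation**. Each variable is reduced to one value per day
   per tree: daylight mean sap flow; daily 95th/5th nearest-rank
   percentiles of stem water content; daily means of VPD, irradiance, leaf
   water potentials and gas exchange; soil moisture averaged over the
   measured depths (10/30/50 cm); cumulative leaf loss; and mean water
   uptake depth from the isotope inversion. Sampling-day-only variables
   are *missing*, never zero, on other days.
3. **Uptake-depth inversion** (`isotope_tools`). See below.
4. **Mutual information** (`infotheory`). Plug-in (maximum-likelihood)
   Shannon estimates, log base 2, on discretized daily values, computed
   for the full experiment and separately for the drydown (days before
   rewatering) and recovery strata.

`soil_hydraulics` supports the chain with a bimodal (two-pore-system) van
Genuchten retention model for converting between soil water content and
water potential.

## Mutual information estimator

With sampling-day variables observed on as few as 5 (full), 3 (drydown)
or 2 (recovery) days, estimator settings dominate the numbers. All are
explicit in `EstimatorConfig`:

- **Binning**: quantile (rank) binning, ties broken by original index;
  default 2 bins, so MI is bounded by 1 bit and monotone-transform
  invariant. Equal-width binning is available.
- **Base**: bits (log2).
- **Bias**: no correction by default; Miller–Madow optional.
- **Pairing**: pairwise-complete same-day pairs only; no lagged pairs.
- **Pooling**: `mean` (across-tree daily means; one sample per day) or
  `tree` (each tree-day is a sample). The `tree` mode is the only
  non-degenerate choice for the two-day recovery stratum — with two
  samples and quantile bins, MI on across-tree means is identically
  maximal — so period comparisons (and the acceptance benchmarks) use
  `pooling="tree"` with 3 bins (18 drydown and 12 recovery tree-days).
  Site-level variables (VPD, irradiance) are duplicated across trees and
  are better interrogated in `mean` mode.

Absolute MI values from data this small are bias-dominated
(plug-in bias ≈ (k−1)²/(2n ln 2) bits); the package's own checks therefore
rest on exhaustively verifiable identities, a dichotomized-Gaussian closed
form, and *relative* (period-contrast) patterns, not on absolute levels.

## Retention model

θ(ψ) = θr + (θs − θr) · Σᵢ wᵢ [1 + (αᵢ|ψ|)^nᵢ]^(−mᵢ) with the Mualem tie
m = 1 − 1/n (the conventional constraint; the data cannot identify m and n
separately at this sample size). Pressure is kPa internally (converters to
MPa provided). Fitting is bounded trust-region least squares on θ
residuals — θr ∈ [0, 15] %, θs ∈ [20, 70] %, α ∈ [10⁻⁴, 10] kPa⁻¹ on a log
scale, n ∈ (1, 10] — with 10 seeded multi-starts and best-RMSE selection;
the two pore systems are reported coarse-first (α₁ ≥ α₂) to remove label
switching. Inversion ψ(θ) brackets log₁₀|ψ| and solves by Brent's method;
round-trips close to better than 1e−8 relative.

## Uptake-depth mixing inversion

Root water uptake is treated as non-fractionating, so a stem water sample
is a convex mixture of soil-layer source waters. With layer signatures
(δD_l, δ¹⁸O_l) and stem pair b, the inversion solves

    min_f ‖A f − b‖² + λ‖Δf‖²   s.t.  f ≥ 0, Σ f = 1,

where A stacks the per-layer pairs with each isotope divided by its
instrument precision (defaults 1.3 ‰ δD, 0.52 ‰ δ¹⁸O, infrared
spectrometry), and Δ is the first-difference operator across adjacent
depths (uptake profiles are smooth in depth). λ defaults to an L-curve
(maximum-curvature) selection over a log grid; the solver is SLSQP on the
simplex. Mean uptake depth is Σ f_l d_l over layer mid-depths (10-cm
layers, positive downward). Mixing is delta-linear; over the tracer ranges
used the deviation from ratio-linear mixing is far below instrument
precision.

A two-equation, six-layer problem is underdetermined in f, but the mean
depth is well constrained whenever the layer signatures vary
quasi-monotonically with depth — which the dual-tracer design (enriched
¹⁸O at the surface, enriched D at ~29 cm, on top of an
evaporation-enriched-to-depleted background gradient) deliberately
produces. A stem pair whose precision-scaled misfit exceeds 3 units lies
outside the soil mixing hull and is flagged infeasible; the
nearest-feasible fractions and depth are still reported, because that
signature (post-rewatering stem water more ¹⁸O-enriched than any soil
source) is itself diagnostic of within-plant storage carryover.

## Synthetic experiments

The generator (`synthetic_data`) is not a soil-physics simulator; it is a
layered bucket model built to produce data with the statistical structure
the analysis stages need, with known ground truth. Design constants
(tracer compositions and volumes, timeline, sampling days, six replicate
trees, organ P50s of −2.53/−1.48 MPa) follow the emulated study design;
dynamical constants are package choices sized so the outputs fall in the
observed ranges (daily VPD maxima 0.75–1.75 kPa, irradiance peaking near
1000 W m⁻², soil moisture 5–40 %, predawn potentials 0 to −1.5 MPa,
transpiration a few litres per day, ~30–60 % leaf loss).

Mechanics, per 15-min step and tree:

- **Meteorology**: sinusoidal diurnal cycles with uniform day-to-day
  jitter; RH is derived from the target VPD curve so VPD, T and RH are
  exactly consistent under the Tetens-type saturation formula
  e_s(T) = 0.61078·exp(17.2694 T/(T+237.3)) kPa.
- **Soil**: six 10-cm layers over a 0.08 m³ column. Layer wetness maps to
  water potential through ψ = −a·w^(−b) (a=0.05 MPa, b=2): a deliberately
  simple stand-in with the right shape. Watering events infiltrate
  piston-like, filling layers to saturation from the application depth
  downward; excess drains and is booked as outflow.
- **Plant**: transpiration demand = g·VPD·light·f_gs(ψ_stem)·s(t), drawn
  from a finite stem capacitor (2500 cm³) that refills from the soil down
  a potential gradient; the refill lag produces the diurnal stem-water
  drawdown and gives the stem isotope pool a finite residence time.
  Per-layer uptake weight ∝ root fraction (exponential profile, 20-cm
  e-folding) × layer wetness. Uptake and evaporation are
  non-fractionating; all pools mix delta-linearly, so water and
  heavy-isotope budgets close to float precision by construction.
- **Stress legacy**: s(t) ∈ [0,1] decays where midday leaf potential drops
  below −0.7 MPa and relaxes back to 1 with time constant
  `legacy_tau_days` (default 16 d), but each tree starts relaxing only
  after a lag proportional to its own time constant. This reproduces the
  delayed, partial and *tree-variable* sap-flow recovery while predawn
  potential recovers within a day of rewatering — the decoupling the
  period-stratified MI analysis is designed to detect. As τ → 0 the lag
  and the suppression both vanish and the trajectory converges to the
  no-stress-memory run.
- **Leaf loss**: a damage pool integrates the same stress signal and
  decays (3 d); shedding is proportional to it with a saturating cap at
  65 % of initial leaf area, so most shedding follows rewatering.
- **Observation model**: heat velocity = flux/sapwood area + 0.5 cm h⁻¹
  offset (so baseline correction is exercised), Gaussian sensor noise,
  isolated spikes (rate 0.18, amplitudes scaled to the series' spread;
  tuned so ~14 % of points end up Hampel-replaced) and rare large negative
  excursions (rate 0.004, values in −10 to −30 cm h⁻¹); sampling-day
  tables carry instrument-grade noise (0.05 MPa on potentials, 0.8 % on
  the soil probe, 1.3/0.52 ‰ infrared and 0.81/0.071 ‰ mass-spectrometry
  isotope precision). Spike perturbations that would cross the excursion
  threshold are flipped positive so the two artifact classes stay
  separable and injection masks remain exact ground truth.

Across-tree heterogeneity (lognormal conductance ×1.25, legacy τ ×1.8,
initial moisture ±1.5 %) is what makes the recovery stratum genuinely
decouple: recovering trees draw down their own soil, so without
heterogeneity any two-day stratum aligns by day in both variables and MI
is spuriously maximal.

### What the synthetic tests do not show

The generator shares no code with the analysis stages it validates, but it
also omits much of real data: no Richards-equation redistribution or
hysteresis, no evaporative isotope fractionation (surface enrichment is
imposed as an initial gradient, not generated), no xylem embolism, no gap
structure or sensor drift beyond the modelled artifacts, and gas exchange
is generated from the same stomatal factor that drives transpiration
(so their mutual information with flux is optimistic). Passing recovery
tests demonstrates estimator and pipeline correctness under the assumed
statistical structure — not that the structural assumptions hold in any
particular field dataset.

## Numerical choices and degenerate inputs

- Hampel: centred window, half-width 6 points (±1.5 h at 15-min data),
  3 scaled MADs with consistency constant 1.4826, truncated windows at the
  edges, decisions on original values; a zero-MAD (constant) window flags
  any deviation.
- Negative-excursion threshold: −5 cm h⁻¹ default, configurable.
- Daylight: irradiance > 10 W m⁻² (a fixed-clock rule is provided).
- Daily cells require ≥ 75 % of expected points, else missing with a
  warning.
- Percentiles: nearest-rank (no interpolation).
- Constant series under quantile binning: single bin, zero entropy, with
  a warning. Fewer than 3 complete pairs: MI flagged unreliable, not an
  exception. Empty period strata produce no rows.
- MI is computed by both H(X)−H(X|Y) and H(X)+H(Y)−H(X,Y) and the routes
  must agree to 1e−12; negatives beyond −1e−12 are an internal error.
- Wound correction: scalar multiplier, default 1.0.
- CSVs are written with `%.17g` floats and read with round-trip parsing,
  so save/load cycles and repeated seeded runs are byte-identical.

## Known limitations

- The uptake-depth inversion reports one depth per stem sample; it cannot
  resolve multimodal uptake profiles, and under storage carryover the
  (flagged) depth reflects stored, not current, water.
- Plug-in MI on ≤ 18 samples has bias comparable to small true signals;
  only large contrasts (such as the drydown-vs-recovery pattern) are
  meaningful, and they are assessed across repeated seeded experiments.
- The bucket model's potentials are internally consistent but not
  calibrated to any retention curve; the `soil_hydraulics` module is fit
  to its own generated curves, not to the bucket model.
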