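# drydown

Analysis toolkit for **drydown–rewatering experiments** on instrumented
plants: it turns raw soil–plant–atmosphere measurements into cleaned flux
and state series, daily summary variables, and period-stratified
mutual-information tables that quantify how well each measurement
constrains plant water fluxes and plant water status.

It is aimed at plant ecophysiologists and ecohydrologists working with
multi-sensor campaigns: 15-min meteorology (T, RH, irradiance), heat-pulse
sap flow and stem water content per tree, and intensive sampling days with
leaf water potentials, depth-resolved soil moisture, and stable water
isotopes (δD, δ¹⁸O) of soil and stem water — optionally with enriched
isotope tracers applied at distinct depths.

## What it computes

- **Sensor cleaning** — negative-excursion removal, heat velocity → sap
  flux via sapwood area, Hampel outlier replacement (rolling median, MAD
  criterion), baseline correction to the no-transpiration minimum.
- **VPD** from temperature and humidity,
  `vpd = e_s(T)·(1 − RH/100)` with
  `e_s(T) = 0.61078·exp(17.2694·T/(T+237.3))` kPa.
- **Soil water retention** — bimodal van Genuchten model
  `S_e(ψ) = Σᵢ wᵢ [1 + (αᵢ|ψ|)^nᵢ]^(−mᵢ)`, `mᵢ = 1 − 1/nᵢ`: evaluation,
  bracketed inversion ψ↔θ, and seeded multi-start bounded least-squares
  fitting.
- **Isotope tools** — delta notation
  `δ = (R_sample/R_standard − 1)·1000` (VSMOW standard), delta-linear
  mixing, and a constrained dual-isotope inversion
  `min_f ‖Af − b‖² + λ‖Δf‖²` on the simplex that yields per-layer uptake
  fractions and the **mean water-uptake depth** `Σ f_l d_l`; stem samples
  outside the soil mixing hull are flagged (a storage-carryover
  signature).
- **Mutual information** — plug-in estimator in bits,
  `I(X;Y) = H(X) − H(X|Y)`, on quantile-binned daily values, for the full
  experiment and separately for the drydown and recovery periods.
- **Synthetic experiments** — a generator with known ground truth (layered
  bucket soil, stem capacitor, dual tracers, stress-legacy mechanism,
  sensor artifacts) so every stage is verifiable without any downloads.

## Worked example

```python
import warnings; warnings.filterwarnings("ignore")
from drydown.pipeline import PipelineConfig, run_pipeline
from drydown.synthetic_data import ExperimentConfig
from drydown.infotheory import EstimatorConfig

config = PipelineConfig(
    synthetic=ExperimentConfig(seed=1),      # 6 trees, 16 days, dual tracers
    output_dir="drydown_output", seed=1,
    mi=EstimatorConfig(pooling="tree", n_bins=3),
)
result = run_pipeline(config)

mi = result.mi
rows = mi[(mi.measurement == "soil_moisture") & (mi.target == "sap_flow")]
print(rows[["period", "mi_bits", "n"]].to_string(index=False))

day12 = result.uptake_depths.query("day == 12")
print(day12[["tree_id", "uptake_depth_cm", "feasible"]].round(1).to_string(index=False))
```

prints

```
  period  mi_bits  n
    full 0.673160 30
 drydown 0.918296 18
recovery 0.251629 12
tree_id  uptake_depth_cm  feasible
     T1             27.5     False
     T2             29.1     False
     T3             28.6     False
     T4             28.3     False
     T5             29.9     False
     T6             30.2     False
```

Reading this: during the imposed drydown, soil moisture is highly
informative about sap flow (0.92 of a possible ~1.58 bits across 18
tree-days); after rewatering the two decouple (0.25 bits) because flux is
governed by a stress legacy rather than by water availability. On day 12
— two days after rewatering, while sap flow is still minimal — every
tree's stem water lies *outside* the soil mixing hull (`feasible=False`):
the stems still carry tracer-enriched water stored before rewatering, so
the nearest-feasible uptake depths (~28–30 cm) describe stored water, not
that day's uptake.

All intermediates (dataset CSVs, per-tree and pooled daily summaries, the
MI table, uptake depths, a processing report with removal/replacement
fractions, and a run report with config hash and file checksums) are
written under `drydown_output/`. Runs are byte-identical given the same
seed.

A CLI mirrors the library: `drydown simulate | process | retention fit |
uptake-depth | mi | run`.

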