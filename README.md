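# vocscreen

Data-processing toolkit for multi-cuvette plant volatilome screening
platforms: a forward simulator of flow-through cuvette gas dynamics and
the inverse pipeline that turns multiplexed sensor logs into
leaf-area-normalized VOC emission, net CO₂ assimilation and transpiration
rates, plus the supporting calculations (air-exchange time constants,
evaporative-cooling energy balance, PTR-MS ion m/z assignment, leaf-area
calibration).

## What it does

A screening platform encloses potted plants in flow-through cuvettes
(volume *V*, inlet flow *F*<sub>in</sub>). Downstream analyzers sample the
cuvettes sequentially through a valve multiplexer. This package covers the
whole processing chain:

- **`vocscreen.cuvette`** — well-mixed mass-balance model
  `dc/dt = E(t)·A_leaf/V + (F_in/V)(c_in − c)`: forward ODE simulation,
  time constant τ = V/F_in, air-exchange fraction 1 − e^(−t/τ), and the
  steady-state (`E = F_in/A_leaf·Δc`) and dynamic (storage-term corrected)
  emission inversions.
- **`vocscreen.signals`** — demultiplexing of valve-switched logs with
  tubing-lag discard, cubic-spline empty-cuvette background correction,
  inlet/outlet series alignment.
- **`vocscreen.gasexchange`** — net CO₂ assimilation and transpiration
  from inlet/outlet differences, bare-soil reference correction,
  psychrometrics (Magnus saturation pressure, absolute humidity, moist-air
  density and heat capacity, Clausius–Clapeyron latent heat) and the
  evaporative-cooling temperature depression
  ΔT = E_s·A·H_v/(ρ_air·F_in·c_p).
- **`vocscreen.ions`** — theoretical ion m/z for the PTR-MS ionization
  channels (protonation, charge transfer, hydride/hydroxide abstraction,
  NO⁺ clustering) in the conventional label convention (whole-atom masses)
  or the exact physical convention, plus tolerance-based peak assignment.
- **`vocscreen.leafarea`** — greenish-pixel counting (HSV hue window),
  linear pixel→area calibration, cubic-spline leaf-area interpolation over
  the experiment.
- **`vocscreen.synth`** — synthetic experiment generator (24-cuvette
  layouts with plant / empty-background / bare-soil roles, diurnal
  profiles, contaminant drift, valve multiplexing, channel noise) with
  full ground truth for parameter-recovery testing.
- **`vocscreen.pipeline`** — the end-to-end chain
  demux → background correction → flux inversion → soil-corrected gas
  exchange → leaf-area-normalized rate tables + run report.

## CLI

A `vocscreen` console script exposes the workflow:

```sh
# synthesize a 24-cuvette experiment with ground truth
vocscreen simulate --seed 1 --out sim/

# full processing chain on any log + config + inlet table
vocscreen pipeline --config sim/config.yaml --log sim/log.tsv \
    --inlet sim/inlet.tsv --out rates/

# individual stages
vocscreen demux --log sim/log.tsv --config sim/config.yaml --out demuxed/
vocscreen correct --target demuxed/c01_voc1.tsv \
    --background demuxed/c19_voc1.tsv --out corrected.tsv
vocscreen flux --outlet corrected.tsv --config sim/config.yaml --out flux.tsv
vocscreen gasx --co2-in 400 --co2-out 390 --rh-in 0.5 --rh-out 0.6 \
    --flow-lpm 6 --leaf-area 0.05
vocscreen leafarea count plant.png
vocscreen mz --formula C10H16 --mode protonation     # -> 137.133
```

Exit codes: 0 success, 1 validation error, 2 runtime error. All tables
are tab-separated text with header rows; configuration is YAML (see
`vocscreen.pipeline.load_config` for the schema).

## Notes

- Flows are entered in L·min⁻¹ and volumes in liters (mass-flow-controller
  conventions) and converted to SI internally; VOC emission rates are
  reported in nmol·m⁻²·s⁻¹ per one-sided leaf area, assimilation in
  µmol·m⁻²·s⁻¹ (uptake positive), transpiration in mmol·m⁻²·s⁻¹.
- The energy-balance ΔT takes air density and heat capacity as explicit
  inputs; `air_density`/`moist_air_cp` helpers implement standard
  psychrometrics, which differ from some tabulated example values.
- Background splines default to the not-a-knot boundary condition so that
  polynomial drifts up to cubic order are removed exactly.
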