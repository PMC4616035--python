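# fluvialghg

Tools for analysing paired measurements of the partial pressure of CO₂
(pCO₂) and dissolved CH₄ in tropical river channels, and for upscaling
river and stream CO₂ evasion to a tropics-wide total with Monte Carlo
error propagation.

Lowland tropical rivers such as the Amazon and the Congo are strongly
supersaturated in both gases relative to the atmosphere, and the wetlands
fringing their channels (flooded forest, floodplain lakes, macrophyte
meadows) are a major carbon source to the water. This package implements
the full analysis chain a biogeochemist needs to work with such data:

- **Gas physics** — the CO₂ solubility coefficient α(T, S) (Weiss-form
  polynomial), the air–water flux `F = k · α · ΔpCO₂`, and the two-phase
  mass balance that recovers a dissolved CH₄ concentration from a
  headspace-equilibration GC measurement.
- **Measurement statistics** — validation and stratification of records
  into mainstem (MS), large tributaries (T>100m) and small tributaries
  (T<100m); box-plot order statistics; Kruskal–Wallis and Mann–Whitney
  comparisons; per-stratum regressions of log₁₀(CH₄) on pCO₂.
- **Wetland regression** — per channel class, an unweighted OLS of each
  basin's median pCO₂ on the wetland fraction of its catchment, with full
  coefficient covariance (`WetlandRegression`, a scikit-learn estimator).
- **Upscaling** — the fitted lines applied over a COSCAT-structured table
  (gas transfer velocity k, water surface area and wetland fraction per
  catchment unit and channel size class); fluxes at 25 °C and 390 ppm
  atmospheric pCO₂, summed over the ±30° latitude band
  (`TropicalUpscaler`).
- **Uncertainty** — Monte Carlo propagation of regression-coefficient,
  k (±10%) and surface-area (±31%) errors to the tropical total.
- **Synthetic data** — generators for measurement tables and COSCAT
  tables with known ground truth, so the entire pipeline is testable
  end to end without external data.

## Worked example

```python
import fluvialghg as fg
from fluvialghg.simulate import CoscatSimConfig, MeasurementSimConfig, StratumConfig

alpha = fg.co2_solubility(25.0)
print(f"alpha(25 C) = {alpha:.4f} mol L-1 atm-1")
print(f"F(k=1, pCO2=1390) = {fg.co2_flux(alpha, 1.0, 1390, 390):.1f} mmol m-2 d-1")
print(f"CH4 from 10 ppm headspace = "
      f"{fg.headspace_to_dissolved_ch4(fg.HeadspaceSetup(10.0)):.1f} nmol L-1")

# study-shaped two-basin data-set (Amazon n=136, Congo n=280)
df = fg.generate_measurements(fg.study_preset(seed=0))
s = fg.summarize(df, "Congo", "T<100m")
print(f"Congo small tributaries: n={s.n}, median pCO2 = {s.pco2_median:.0f} ppm")

# six synthetic basins on known pCO2-wetland lines, then upscale
true = {"MS": (1500.0, 20000.0), "T>100m": (2000.0, 22000.0), "T<100m": (3000.0, 28000.0)}
wet = {"B1": 0.01, "B2": 0.05, "B3": 0.10, "B4": 0.14, "B5": 0.22, "B6": 0.32}
strata = tuple(
    StratumConfig(b, cls, 50, true[cls][0] + true[cls][1] * w, 1.5, 5e-5, 2.5, 0.3)
    for b, w in wet.items() for cls in fg.CHANNEL_CLASSES
)
basins = fg.generate_measurements(MeasurementSimConfig(strata=strata, seed=11))
up = fg.TropicalUpscaler().fit(fg.build_basin_points(basins, wet))
m = up.models_["T<100m"]
print(f"T<100m regression: pCO2 = {m.intercept_:.0f} + {m.slope_:.0f} * wetland, r2 = {m.r2_:.3f}")

cells, true_total = fg.generate_coscat(CoscatSimConfig(n_cells=60, seed=3))
print(f"deterministic tropical total = {up.total(cells):.3f} PgC yr-1 "
      f"(generator truth {true_total:.3f})")
res = fg.mc_propagate(cells, up.models_, config=fg.McConfig(n_iterations=1000, seed=42))
print("Monte Carlo:", fg.summarize_mc(res, rounding=2))
```

Output:

```
alpha(25 C) = 0.0340 mol L-1 atm-1
F(k=1, pCO2=1390) = 34.0 mmol m-2 d-1
CH4 from 10 ppm headspace = 286.6 nmol L-1
Congo small tributaries: n=90, median pCO2 = 7304 ppm
T<100m regression: pCO2 = 3204 + 27067 * wetland, r2 = 0.972
deterministic tropical total = 0.239 PgC yr-1 (generator truth 0.236)
Monte Carlo: 0.24 ± 0.08 [0.10, 0.40] PgC yr⁻¹
```

Reading: at 25 °C a 1000 µatm supersaturation drives 34 mmol CO₂ m⁻² d⁻¹
per m d⁻¹ of gas transfer velocity. The fitted small-stream line recovers
the generating slope (28 000 ppm per unit wetland fraction) within its
standard error; upscaling the fitted lines over the synthetic COSCAT table
reproduces the known tropical total within ~1%, and the Monte Carlo places
the truth comfortably inside the 95% interval. The interval is dominated
by the ±31% surface-area uncertainty because errors are treated as fully
correlated across catchment units.

A command-line entry point `fluvial-ghg` wraps the same steps
(`simulate`, `summarize`, `test`, `upscale --mc`).

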