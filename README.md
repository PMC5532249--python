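# domcarbon

Dead organic matter (DOM) — woody debris plus litter — is the least-measured
carbon pool in national forest carbon budgets. `domcarbon` implements a
complete accounting pipeline for estimating DOM carbon stocks and their
change over forest-inventory periods, from raw field-plot measurements to
gridded ensemble predictions with Monte-Carlo uncertainty:

1. **Plot accounting** — dead-wood piece measurements (snags, logs, fine
   woody debris), litter subplots, tree tallies and soil profiles become
   per-site carbon densities (Mg C ha⁻¹). Unweighable pieces use the
   cylinder volume *V = πd²L/4* times a species × decay-class density ratio;
   litter and wood become carbon via decay-class carbon concentrations
   (default 0.5); stand age is the age of the fifth-largest tree by DBH.
2. **Predictor surfaces** — inventory timber volume per province × forest
   type becomes above-ground biomass carbon through the biomass expansion
   factor *BEF = a + b/x* (x = volume per hectare), painted onto a 0.083°
   forest-type raster; station climate records are kriged to the same grid.
3. **Ensemble upscaling** — for each DOM component (FWD, snags, logs,
   litter), repeated resampling (70 % train / 30 % validation) of Random
   Forest models on the site data; every member predicts every grid cell, so
   the between-member spread is the Monte-Carlo uncertainty of each pixel,
   region, and the national stock (stock = density × area; 1 Mg C ha⁻¹ over
   1 Mha = 1 Tg C). Derived pools are summed per member (CWD = snags + logs,
   woody debris = FWD + CWD, DOM = woody debris + litter), keeping reported
   means exactly additive.
4. **Trends** — ordinary-least-squares change rates of density and stock
   over the inventory-period midpoints (1986, 1991, 1996, 2001, 2006), the
   component partition of the DOM sink, and one-way-ANOVA group comparisons
   with Tukey-HSD compact letters.

A synthetic-world generator (`domcarbon.synth`) emits every pipeline input —
raw plot files, inventory and BEF tables, station records, the forest-type
raster — from known true response surfaces, so each stage is testable by
recovery against truth.

## Worked example

```python
from domcarbon.pipeline import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(seed=1, n_members=50))
pt = result.period_table
print(pt[pt.component == "dom"][["period", "density_mean", "stock_mean", "stock_sd"]])
```

```
   period  density_mean  stock_mean  stock_sd
1984-1988          6.06      797.60      7.41
1989-1993          6.14      844.68      5.82
1994-1998          6.18      887.35      5.80
1999-2003          6.25      934.55      6.60
2004-2008          6.24      969.17      7.25
```

Each row is the national DOM carbon density (Mg C ha⁻¹) and stock (Tg C,
mean ± between-member SD) for one inventory period of the synthetic world.
The generator's true 2004–2008 stock for this seed is 978 Tg, so the
ensemble recovers the national stock within about 1 %. The fitted trend
(`result.trends`) gives the DOM stock change rate ≈ 8.6 Tg C yr⁻¹ against a
configured truth of 9.2, and `result.partition` splits it ≈ 60 % woody
debris / 40 % litter.

The same run is available from a shell:

```bash
domcarbon upscale --seed 1 --n-members 50 --out artifacts/
domcarbon synth --seed 1 --out world/        # input files + truth.json only
domcarbon roundtrip --seed 1                 # raw-measurement decomposition check
```

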