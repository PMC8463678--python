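# isodendro

Tree-ring stable-isotope chronologies and climate reconstruction for
dendroclimatology: from per-tree δ¹³C/δ¹⁸O cellulose series to a verified,
annually resolved reconstruction of a climate variable, with extreme-year
and volcanic-forcing analysis.

The package is aimed at paleoclimatologists working with subarctic conifer
isotope records — settings where a handful of overlapping trees per year
must be averaged into a millennium-long chronology, screened against a short
instrumental record, and pushed back in time through a linear transfer
function.

## What it computes

**Chronology.** Per-tree series are trimmed of their first 50 rings (the
possible juvenile period), then averaged year by year with equal weights.
Years covered by fewer than 4 trees are dropped, never interpolated.

**Suess correction.** Raw δ¹³C carries the industrial-era decline of
atmospheric δ¹³C(CO₂). The correction subtracts, for each year t ≥ 1850, the
difference between the atmospheric record and its pre-industrial value:
corrected(t) = raw(t) − (δ¹³C_atm(t) − δ¹³C_atm(1850)). The applied deltas
are returned so the correction is exactly invertible.

**Transfer function.** Inverse calibration by ordinary least squares, with
the climate variable as the dependent variable and the isotope chronology
as the predictor:

    Rec_t = a · I_t + b + ε_t

Split-period calibration/verification reports, on the withheld window:

- r — Pearson correlation of observed and reconstructed values,
- RE = 1 − Σ(obs−rec)² / Σ(obs−mean_cal)² (reduction of error),
- CE = 1 − Σ(obs−rec)² / Σ(obs−mean_ver)² (coefficient of efficiency, ≤ RE),
- DW = Σ(e_t−e_{t−1})² / Σe_t² (Durbin–Watson, residual autocorrelation),
- Ks — Gleichläufigkeit, the fraction of adjacent year-pairs whose observed
  and reconstructed changes share a sign (ties count ½).

Coefficient uncertainty comes from a seeded residual bootstrap (2.5/97.5
percentiles); the reconstruction carries a 95 % band of ±1.96 × calibration
residual RMSE.

**Extremes.** Reconstructions are smoothed with normalized Hamming windows
(41- or 101-year); years beyond ±2σ (±3σ) of a reference mean are flagged,
period means and trends contrasted, and negative extremes matched against a
catalog of explosive eruptions (VEI ≥ 4) within a configurable lag window.

**Pseudoproxies.** `isodendro.synthetic` generates the whole input stack —
monthly AR(1) station climate about a subarctic climatology (July mean
12.6 °C, ≈280 mm/yr precipitation), an atmospheric δ¹³C record with a
2 ‰ post-1850 decline, and 42 overlapping tree series with tree-level
offsets, juvenile ramps, 0.2 ‰ measurement noise and the Suess imprint —
with every ground-truth parameter recorded, so the full pipeline is testable
without any external data.

## Worked example

```python
import isodendro as iso

ds = iso.generate_dataset(seed=1)                      # 42 synthetic trees, 516–2009 CE
chron = iso.build_chronology([iso.trim_juvenile(t) for t in ds.trees])
stats = iso.summary_stats(chron, (516, 2009))

proxy, _ = iso.correct_suess(chron.mean, ds.atm)       # remove the Suess decline
target = ds.climate.aggregate("precipitation", [7], stat="sum")
report = iso.calibrate_full(proxy, target, (1990, 2009), (1969, 1989), seed=1)
rec = iso.apply_transfer(report.final_model, proxy).loc[516:2009]["reconstruction"]
extremes = iso.detect_extremes(rec)
```

This prints (via the accompanying `print` statements):

```
chronology 516-2009: mean -25.0 permil, SD 0.84, SE 0.022, n 1494
transfer function: P_July = -16.70 * d13C + -370.13  (r = -1.00, truth slope -16.7)
verification 1969-1989: r 1.00  RE 0.99  CE 0.99  DW 1.44  Ks 0.95
reconstruction: 1494 years, mean 45.8 mm, SD 13.5 mm
extremes: 71 years beyond 2 sigma, of which 31 dry
```

The 1494-year July-precipitation reconstruction recovers the generator's
transfer slope of −16.7 mm/‰ almost exactly; RE and CE near 1 say the model
beats both no-skill reference forecasts on the withheld 1969–1989 window;
DW near 2 would indicate uncorrelated residuals; 71 years depart from the
long-term mean by more than two standard deviations.

The same pipeline runs from the shell:

```sh
isodendro run-all --out results/          # synthetic end-to-end run
isodendro simulate --out data/ --seed 7   # just the pseudoproxy dataset
isodendro chronology --trees data/trees.csv --out chron.csv
```

Bundled reference transfer models (`july_precipitation` from δ¹³C, `ao_may`
— the May Arctic Oscillation index — from δ¹⁸O) can be applied to any proxy
series with `iso.load_reference_model(name)` or
`isodendro reconstruct --reference-model july_precipitation ...`.

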