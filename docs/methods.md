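# Methods

## The reconstruction model

The pipeline treats a tree-ring isotope chronology I_t (δ¹³C or δ¹⁸O of
cellulose, ‰) as a linear recorder of one climate variable and inverts that
relation by inverse calibration: the climate variable is regressed on the
proxy over an instrumental window,

    Rec_t = a · I_t + b + ε_t,

and the fitted line is applied over the full proxy span. The approach
assumes (i) a stationary, linear proxy–climate relation over the whole
reconstruction period ("uniformitarianism"), (ii) that averaging ≥ 4 trees
per year suppresses tree-level noise enough for the chronology to track the
common climate signal, and (iii) that the only systematic non-climatic
trend in δ¹³C is the atmospheric Suess decline, which is removed by
subtraction before calibration (no other standardization is applied).

Fitted transfer models keep the OLS intercept and an `extra_offset` term
separate. Freshly fitted models always have `extra_offset = 0`; the bundled
reference models carry a small published additive constant (+0.15) in that
slot, preserved verbatim rather than folded into the intercept because its
provenance is not documented with the coefficients.

## Skill statistics

Verification on a withheld window uses the standard dendroclimatological
battery. RE compares squared errors against the *calibration*-period
observed mean as a no-skill forecast; CE against the *verification*-period
mean. Since the verification mean minimizes the squared-error denominator,
CE ≤ RE always; both > 0 indicate skill. DW is the Durbin–Watson statistic
of the verification residuals in chronological order (2 ≈ uncorrelated; a
perfect fit with zero residuals is reported as the neutral 2 rather than
0/0). Ks (Gleichläufigkeit) scores sign agreement of year-to-year changes,
with zero first-differences contributing ½ — the common convention.
Two-sided p-values for Pearson correlations use the t-transform.

Coefficient percentiles (2.5/97.5) come from a residual bootstrap of the
union-period fit: calibration residuals are resampled with replacement onto
the fitted values and the OLS solved per resample (1000 draws by default,
seeded). The reconstruction's 95 % band is the constant ±1.96 × calibration
residual RMSE; a constant band understates uncertainty far from the
calibration mean but is transparent and matches how such reconstructions
are usually displayed.

The split windows default to calibration 1990–2009 and verification
1969–1989. Where the two windows abut, the boundary year is assigned to
calibration only; both windows are configurable.

## The pseudoproxy generator

`isodendro.synthetic` emulates a subarctic larch site with a single nearby
weather station, not any real dataset. Its defaults are the study
conditions every test and the acceptance script run under:

| parameter | default | meaning |
|---|---|---|
| year span | 516–2009 CE | 1494-year post-juvenile chronology |
| n_trees | 42 | overlapping series, ≥ 4 everywhere |
| target | July precipitation (mm) | climate variable driving δ¹³C |
| transfer slope | −16.7 mm/‰ | ground truth; proxy slope is its reciprocal |
| proxy intercept | ≈ −22.27 ‰ | puts the chronology mean near −24.9 ‰ |
| tree_sd | 0.15 ‰ | between-tree offset SD (free parameter; unreported in the field for this design, chosen as a plausible within-stand spread) |
| noise_sd | 0.2 ‰ | analytical measurement precision |
| juvenile ramp | 0.3 ‰ over 50 rings | linear decay to zero at ring age 50 |
| AR(1) coefficient | 0.3 | interannual persistence of climate anomalies |
| innovation scales | 1.5 °C, 30 % of monthly climatology (precip), 1.0 (AO) | anomaly amplitudes at `innovation_sd = 1` |
| volcanic cooling | 1.5 °C | temperature depression in eruption year and the next |

The monthly climatology is a cosine temperature cycle with annual mean
−12.8 °C peaking at 12.6 °C in July, and 280 mm/yr of summer-weighted
precipitation (July 44 mm). With these defaults the July-precipitation
signal imprinted on the proxy has SD ≈ 0.8 ‰, so the synthetic chronology
reproduces the scale of real subarctic δ¹³C chronologies.

Tree lifespans are drawn from a clipped normal (mean 300, SD 60, bounds
80–600 rings). Four "layers" of back-to-back trees, each overlapping its
predecessor by the 50-ring juvenile length, guarantee that after juvenile
trimming at least four trees cover every year of the requested span (the
climate and the trees extend 50 years earlier than the span for this
reason). Remaining trees alternate between living trees anchored at the
modern end of the span — mirroring collections where roughly half the
samples come from standing trees, which keeps the instrumental-era
replication realistic — and randomly placed dead wood. One global seed
fans out to per-tree substreams (`SeedSequence(seed, spawn_key=(i,))`), so
adding a tree never perturbs existing ones and the same seed reproduces the
dataset bit for bit.

The atmospheric δ¹³C record is a −6.4 ‰ plateau through 1850 followed by a
quadratic-in-time decline to −8.4 ‰ at 2009. Only the plateau, the monotone
decline and the ≈2 ‰ total depletion are treated as fixed features; the
quadratic shape is a modelling choice.

What the generator does *not* emulate: spatial coherence across sites,
non-linear or time-varying proxy responses, dating error, heteroscedastic
measurement noise, autocorrelated juvenile behaviour, or precipitation
seasonality shifts. Passing tests therefore demonstrate that the pipeline
recovers known parameters under its own model assumptions — they do not
validate those assumptions for real wood.

## Numerical and design choices

- Sample SD (n−1) everywhere; SE = SD/√n.
- Juvenile trimming counts ring age from the pith year when known, else from
  the series start; series that begin above the juvenile age (broken stems)
  lose nothing.
- Years failing the 4-tree replication gate are dropped, not interpolated;
  trees are averaged with equal weights after sorting by tree id, making the
  chronology exactly invariant to input order.
- The Suess correction records `delta_applied = raw − corrected`, so the
  round-trip identity holds bit for bit; missing atmospheric years are a
  hard error rather than silently interpolated.
- Hamming smoothing uses w_k ∝ 0.54 − 0.46·cos(2πk/(M−1)), normalized to
  sum 1; edges truncate the window to the available years and renormalize,
  fabricating nothing beyond the series ends. Windows must be odd, ≥ 3 and
  no longer than the series.
- Extreme-year z-scores default to the full-period reference; the sign of an
  extreme refers to the reconstructed climate units (dry = negative
  precipitation anomaly), not to the raw isotope sign.
- The volcanic lag window defaults to 0–3 years after an eruption and the
  VEI threshold to 4; the match count is monotone in the window width.
- The transfer fitter is single-predictor (the replication path of the
  published equations); correlation screening covers all 12 months plus
  June–July, July–August, JJA and annual aggregates, using monthly sums for
  precipitation and means otherwise.
- Simulation sizes in tests (e.g. 100 replicates of the 42-tree scenario,
  10 000-year AR(1) checks) were chosen so the statistical assertions have
  comfortable margins while the whole suite stays fast.

## Known limitations

- The constant-width confidence band ignores predictor-extrapolation
  variance.
- RE/CE thresholds (> 0) are necessary, not sufficient, evidence of skill;
  no Monte-Carlo significance benchmarks (e.g. against red-noise proxies)
  are built in beyond the shuffled-null test.
- The generator's linear, single-variable proxy model cannot probe
  multi-variable confounding (e.g. temperature and precipitation jointly
  driving δ¹³C), which real isotope series exhibit.
- Volcanic matching is a window count, not a superposed-epoch analysis, and
  makes no attempt at causal attribution.
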