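# climepi

Time-series and gridded-field tools for climate–epidemiology attribution
studies, built around one recurring analysis pattern: an annual health or
climate series shows a regime change; the change-point is located by a
piecewise linear fit; trends and correlations are tested against a red-noise
null; a multidecadal climate oscillation is extracted by Singular Spectrum
Analysis; and gridded fields (e.g. summer sea-level pressure) are mapped as
per-gridpoint trends and correlations with Monte-Carlo significance masks.

The motivating application is the link between the Atlantic Multidecadal
Oscillation (AMO) — a ~60–80-year oscillation in North Atlantic sea-surface
temperature — and UK rickets incidence through sea-level pressure, cloud
cover and sunshine duration. The observational inputs of such a study
(hospital-episode incidence rates, the NOAA AMO index, Met Office sunshine,
ERA-Interim pressure fields) are not redistributable, so the package ships a
first-class synthetic-data module that plants known structure (break years,
oscillation phase, regional trends and correlations) and the whole pipeline
is validated by recovering it.

## Methods in brief

**Breakpoint detection.** For a candidate break year $b$, two independent
OLS lines are fitted over $[y_0, b]$ and $[b, y_1]$ (the break year belongs
to both segments) and pooled as
$\mathrm{RMSE}(b) = \sqrt{(\mathrm{SSE}_1 + \mathrm{SSE}_2)/(n_1 + n_2)}$.
The break is the candidate minimising RMSE; its uncertainty comes from a
parametric AR(1) bootstrap around the fitted piecewise signal.

**Red-noise significance.** Annual series carry lag-1 autocorrelation
("red noise"), which inflates apparent trends and reduces the effective
degrees of freedom. Significance is therefore Monte-Carlo: an AR(1) process
$x_t = \phi x_{t-1} + \varepsilon_t$ is fitted to the series (to the
detrended series for trend tests, with an exact correction for the moments
detrending removes) and the observed statistic is compared with its
distribution over (by default) 10,000 surrogate series. Trend comparisons
are studentized so the test stays calibrated when $\phi$ is estimated.
Two-sided p-values use the add-one rule, $p \ge 1/(N_{\rm surr}+1)$.
Phase-randomization surrogates are available as an alternative null.

**SSA.** The lag-covariance matrix $\mathbf{X}^\top\mathbf{X}/K$ of the
$K \times M$ trajectory matrix is eigendecomposed (Broomhead–King); each
eigenpair yields a reconstructed component by diagonal averaging, and the
low-frequency (multidecadal) component is the sum of components whose
spectral peak is slower than a cutoff period (default 40 yr).

**Spatial maps.** Monthly fields are averaged over June–August, subset to a
lat/lon box, and reduced per gridpoint to an OLS trend (units/decade) or a
Pearson correlation with an annual index, each with a cell-wise red-noise
significance mask. Domain-mean indices are cosine-latitude weighted.

## Worked example

```python
import climepi as c

series = c.gen_incidence_series(
    c.PiecewiseTrendSpec(1963, 2011, 1997, intercept=0.951,
                         slope_pre=-0.023, slope_post=0.104),
    c.AR1Params(phi=0.3, sigma_e=0.15),
    seed=42,
)
scan = c.scan_breakpoints(series, 1990, 2000, n_bootstrap=1000, seed=7)
print(f"break year: {scan.best_year} +/- {scan.uncertainty_halfwidth:.0f} "
      f"(min RMSE {scan.min_rmse:.3f})")
for y0, y1 in ((1963, scan.best_year), (scan.best_year, 2011)):
    median, trend = c.segment_summary(series, y0, y1)
    sig = c.trend_significance(series.window(y0, y1), n_surrogates=10_000, seed=1)
    print(f"{y0}-{y1}: median {median:.2f}, trend {trend:+.2f}/decade "
          f"(p = {sig.p_two_sided:.4f}, CL {sig.confidence_level_pct:.1f}%)")
```

prints

```
break year: 1995 +/- 1 (min RMSE 0.112)
1963-1995: median 0.61, trend -0.19/decade (p = 0.0001, CL 100.0%)
1995-2011: median 0.92, trend +1.05/decade (p = 0.0001, CL 100.0%)
```

The generator planted a break in 1997 with per-decade trends −0.23 (decline)
and +1.04 (rise) under AR(1) noise; this noise realization locates the break
at 1995 (within the bootstrap's ±3-yr scale for these settings) and recovers
both segment trends with red-noise confidence above 99.9%.

The full study — both breakpoint scans, SSA sign-change extraction, and the
three gridded maps — runs from one config:

```bash
climepi pipeline run --outdir out/          # synthetic defaults
climepi pipeline summarize --report out/report.json
```

Each stage is also exposed on its own (`climepi breakpoint`, `climepi
mctest trend|corr`, `climepi ssa`, `climepi spatial trend|corr`), reading
`year,value` CSVs and `(time, lat, lon)` NetCDF under documented contracts,
so the same pipeline runs on real data files when you have them.

## Layout

- `climepi.synthetic` — seeded generators: AR(1) noise, piecewise-trend
  series, noisy oscillation, gridded field with planted trend/correlation
- `climepi.breakpoint` — segment OLS, piecewise fit, minimum-RMSE scan,
  bootstrap uncertainty
- `climepi.surrogate` — AR(1)/phase-randomization surrogates, trend and
  correlation significance
- `climepi.ssa` — decomposition, reconstruction, low-frequency selection
- `climepi.spatial` — seasonal means, domain subsetting/indices, trend and
  correlation maps, NetCDF I/O
- `climepi.pipeline` — study orchestration and the change-point alignment
  summary
- `docs/methods.md` — model assumptions, parameter choices, numerical
  details and known limitations
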