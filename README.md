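# dermtrends

Infodemiology toolkit for cross-topic analysis of Google-Trends-style
**relative search volume (RSV)** — built around the study design used to
rank public interest in dermatologic clinical signs (itch, hair loss,
skin rash, …) worldwide from monthly search data, and to characterize
each topic's secular trend and seasonality.

Google Trends only reports *relative* interest: each exported series is
rescaled so its own maximum is 100, and values below 1% print as the
censoring token `<1`. Topics exported separately therefore live on
incomparable scales. The toolkit implements the benchmark-anchoring
design that works around this:

* **Imputation.** Censored tokens are mapped to numbers before any
  statistic: `<1` → 0.5 and `0` → 0.1, so ratios stay finite.
* **Benchmark anchoring.** Every topic *T* is exported jointly with a
  fixed reference topic *R* ("Scar"), which puts both on one scale. The
  global popularity of *T* is the ratio of means
  `P(T) = mean(RSV_T) / mean(RSV_R)`, with `P(R) = 1.00` by
  construction. Per country, the compared breakdown gives shares
  `s_T + s_R = 100`, anchored as `RSV*_T = 50 · s_T / s_R` so the
  reference reads 50 everywhere. Countries with fewer than five topics
  of positive RSV are excluded as unreliable.
* **Secular trend.** The Seasonal Mann–Kendall test: within each
  calendar month *g*, `S_g = Σ_{i<j} sgn(x_{g,j} − x_{g,i})` over
  years, `S = Σ_g S_g`, tie-corrected variance
  `Var_g = [n_g(n_g−1)(2n_g+5) − Σ_k t_k(t_k−1)(2t_k+5)]/18`, normal
  approximation with ±1 continuity correction,
  `tau = S / Σ_g n_g(n_g−1)/2`. Trend magnitude is the OLS slope of
  RSV on time in fractional years (RSV/year), reported when the
  Mann–Kendall test is significant.
* **Seasonality.** An additive STL-style decomposition with a
  self-implemented tricube Loess trend smoother and a *periodic*
  seasonal component (one value per calendar month, centred). Reported
  per topic: peak and trough months and the yearly amplitude
  `max(component) − min(component)`. Seasonality presence is decided by
  a harmonic-regression F-test (linear time vs linear time + two
  Fourier harmonics of the annual cycle).
* **Synthetic data.** A seeded generator produces Google-Trends-dialect
  CSVs from a latent model (baseline × popularity ratio + linear trend
  + monthly pattern + December dip + noise) pushed through the GT
  observation transform (max-100 rescaling, rounding, `<1` censoring,
  joint pairwise scaling, per-country shares, low-volume masking), with
  the full ground truth saved alongside for recovery testing.

## Worked example

```python
from dermtrends import make_world_fixture, write_world, AnalysisConfig, run_pipeline

world = make_world_fixture("paper-like", seed=7)   # 34 topics, 72 countries
write_world(world, "demo_data")                    # GT-dialect CSVs + ground truth
cfg = AnalysisConfig(input_dir="demo_data", output_dir="demo_out", seed=7)
res = run_pipeline(cfg)
print(res["proportion_table"].head(5).to_string(index=False))
```

```
       topic  proportion
        itch    2.627428
   skin_rash    1.312207
perspiration    1.147328
        scar    1.000000
   hair_loss    0.978751
```

The proportion column is each topic's mean RSV relative to the
reference topic over 2004–2019; `itch` at 2.63 means Google users
generated about 2.6 times the search interest in itch as in scars, and
the reference row is exactly 1.00 by definition. The trend table
carries the time-series results per topic:

```
    topic  tau stars  slope  seasonal peak_month trough_month  amplitude
cellulite 0.94   ***   2.24      True        May     December      48.57
hair_loss 0.97   ***   3.24     False          -            -        NaN
     itch 0.99   ***   4.91      True       July        April       8.72
```

`tau` is the Seasonal Mann–Kendall rank correlation with time (***:
p < 0.001), `slope` the OLS trend in RSV/year, and `amplitude` the
yearly swing of the seasonal component in RSV units — e.g. cellulite
interest swings ~49 RSV between its May peak and December trough, while
hair loss shows a strong secular rise but no detectable seasonality.
`res["country_table"]` lists each included country's most-searched
topic and top five (12 of the 72 fixture countries are dropped: masked
for low volume or failing the five-positive-topics rule).

The same steps run from the shell: `dermtrends simulate --preset
paper-like --seed 7 --out demo_data` then `dermtrends analyze --config
config.yaml`.

## Layout

| module | role |
| --- | --- |
| `dermtrends.registry` | topic catalogue, reference topic, study period |
| `dermtrends.gt_io` | GT-dialect CSV parsing/writing, censoring imputation |
| `dermtrends.anchoring` | reference anchoring, country rankings, exclusion rule |
| `dermtrends.trend` | Seasonal Mann–Kendall test, OLS slope |
| `dermtrends.seasonality` | Loess smoother, periodic STL, harmonic F-test |
| `dermtrends.simulate` | latent world model, GT observation transform, fixtures |
| `dermtrends.report` | end-to-end pipeline, table/metadata outputs |
| `dermtrends.cli` | `dermtrends` command (simulate/rank/trend/seasonality/analyze) |

See `docs/methods.md` for the statistical details, default parameters,
and known limitations.
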