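# Methods

This note documents the statistical procedures, their assumptions, the
default parameters, and what the synthetic-data generator does and does
not emulate.

## Data model and imputation

Input series are monthly relative search volume (RSV): integers 0–100
with the series (or query-pair) maximum pinned at 100, plus the
censoring token `<1` for nonzero interest below 1%. Before any
statistic, tokens are imputed: `<1` → 0.5 (the midpoint of the censored
interval) and `0` → 0.1 (a small positive floor so ratios against the
benchmark stay finite). Imputation preserves the token ordering
0 < `<1` < 1 ≤ integers. The same rule is applied to region share
tables; this choice is recorded in the pipeline's output metadata
because exports differ in whether region tables ever print `0`.

Only monthly series are accepted; weekly exports are rejected rather
than resampled, since the analysis period (whole years, default
2004-01 to 2019-12, 192 months) and the seasonal machinery assume
calendar-month granularity.

## Benchmark anchoring

Separate Google-Trends exports are not comparable (each is rescaled to
its own maximum), so all topics are compared pairwise against one
reference topic chosen for broad, stable volume. Definitions:

* **Global (time mode).** `P(T) = mean(RSV_T) / mean(RSV_R)` over the
  full period, both series from one jointly-scaled export. The ratio
  of means (rather than the mean of monthly ratios) is robust to
  censored months and is invariant to the joint rescaling; the
  reference's own row is emitted as exactly 1.00 by definition rather
  than recomputed.
* **Region mode.** With compared-breakdown shares `s_T + s_R = 100`,
  the anchored value is `50 · s_T / s_R`, placing the reference at 50
  in every country. Imputation guarantees `s_R ≥ 0.1`.
* **Exclusion.** A country is analyzed only if at least `min_topics`
  (default 5) topics have positive single-topic RSV there; masked
  countries (blank rows) are carried explicitly with their reason so
  exclusions are auditable.
* **Ranking.** Per country, topics sort by anchored value descending;
  ties break by registry order and are flagged; a missing topic is
  scored as an imputed zero share (value 0.05) instead of being
  dropped, which avoids biasing rankings toward popular topics.

## Secular trend

The Seasonal Mann–Kendall test treats each calendar month as a season:
within month *g* the classical Kendall statistic over years is
`S_g = Σ_{i<j} sgn(x_{g,j} − x_{g,i})`, with tie-corrected variance
`Var_g = [n_g(n_g−1)(2n_g+5) − Σ_k t_k(t_k−1)(2t_k+5)]/18`. Seasons are
summed (`S = Σ S_g`, `Var = Σ Var_g`) and treated as independent — the
serial-correlation (inter-season covariance) correction is deliberately
not applied and is listed as an extension. The normal approximation
uses the ±1 continuity correction, so `Z = 0` whenever `|S| ≤ 1`;
`tau = S / Σ_g n_g(n_g−1)/2` with the tie-unadjusted denominator
(oracle comparisons are restricted to tie-free data for this reason).
A fully tied series yields `Z = 0, p = 1` and a degenerate flag.

Calibration at the study's series length (16 years × 12 months): the
acceptance suite measures a null rejection rate of ~4.5% at α = 0.05
over 2,000 white-noise series, and power ≥ 0.995 against a 3 RSV/year
trend with noise sd 2.

Trend magnitude is the OLS slope of RSV on time coded in fractional
years (month index / 12), with the usual t-test on the coefficient.
Slopes are computed for all series but reported as "n/a" when the
Mann–Kendall p ≥ α, mirroring conditional reporting practice. At least
24 months are required.

## Seasonal decomposition

An additive trend/seasonal/remainder split in the STL family, built on
a self-implemented Loess smoother: at each point the
`q = max(degree+1, ceil(span · n))` nearest neighbours are fit by
weighted least squares with tricube weights `(1 − (d/d_max)³)³`
(degree 1 for the trend). The seasonal component is *periodic*: one
fixed value per calendar month, the centred cycle-subseries mean. The
scheme alternates (detrend → monthly means → re-fit trend on the
deseasonalized series) for `n_iterations` outer loops; the remainder is
defined as input − trend − seasonal, so the additive identity is exact
by construction.

Defaults: trend span `max(0.2, 1.5 · period / n)` (≈ 39 months at
n = 192 — wide enough to bridge an annual cycle), 2 outer iterations,
no robustness weighting (an anomalous month can instead be excluded via
configuration). The loop converges geometrically (error contracts by
roughly an order of magnitude per iteration on noise-free input); with
the default 2 iterations the residual trend/seasonal leakage on exact
additive input is below 0.1 RSV, and the decomposition agrees with an
established STL implementation (periodic seasonal window) within
0.5 RSV on fixture data.

Summaries per topic: peak month (argmax of the 12 components), trough
month (argmin), and yearly amplitude = max − min, in RSV units. Month
ties break toward the earliest calendar month and are flagged.

**Seasonality presence** is declared by a harmonic-regression F-test:
nested OLS fits of the series on intercept + linear time, with and
without sine/cosine terms at 1 and 2 cycles per year (4 extra
parameters). This fills the role a TBATS fit plays in declaring a
12-month cycle, at a small fraction of the machinery; the substitution
is stated in the pipeline's output metadata. Null calibration: ~95%
non-rejection at α = 0.05 on trend-plus-noise series.

## Synthetic-data generator

Latent search intensity per topic:
`x_t = max(ε, baseline · ρ + slope · t/12 + pattern[month] + dip · 1[Dec] + N(0, σ²))`
with ε = 0.001, where ρ is the topic's popularity ratio relative to the
reference. The observation transform mimics Google Trends: max-100
rescaling (joint for pairwise queries), integer rounding, `<1` for
values rounding below 1, `0` only for exactly zero intensity,
per-country share tables, and masking of countries whose total volume
falls below a threshold. All randomness flows from integer seeds
through numpy's PCG64 generator; fixtures are bit-reproducible.

The **paper-like** preset has 34 topics with popularity ratios spanning
0.01–2.21 and positive secular slopes — both taken from the observed
study-scale values — warm-month peaks with December troughs for most
topics, and one trending but aseasonal topic (hair loss). Design
choices:

* Trend, seasonal pattern, dip and noise are all scaled by ρ, so the
  whole latent series is proportional to the ratio; the ground truth
  records the exact noise-free ratio of means (`mean_ratio`), which is
  what the anchoring estimator targets when topics differ in trend.
* Seasonal shapes are a fundamental cosine plus a second harmonic and a
  small sine term — sharp, slightly asymmetric warm-season peaks rather
  than pure sinusoids — with latent swings set so observed amplitudes
  land at the study-scale values (≈ 4.5–44 RSV). The December dip
  (20% of the swing) applies except where the topic itself peaks in
  December.
* Noise sd is 2% of the latent peak, i.e. ≈ 2 RSV after rescaling.
* 72 countries with lognormal per-topic weights and volumes; the lowest
  ~10% of volumes mask (emulating GT's low-volume suppression), and
  five countries carry near-zero weight for all but three topics to
  exercise the five-positive-topics exclusion rule.
* Because single-topic exports are rescaled by 100/max, an estimated
  slope in RSV/year corresponds to latent slope × scale; the generator
  records the realized scale factor per series in the ground truth so
  recovery is assessed in observed units.

What the generator does **not** emulate: sampling jitter across
repeated GT downloads of the same query, weekly granularity,
query-language/topic-matching effects, or non-Gaussian burst events
(news-driven spikes). Passing recovery tests therefore show the
pipeline correctly inverts the documented GT transform under realistic
noise — not that real GT exports satisfy the latent model.

## Known limitations

* **Amplitude resolution floor.** The yearly amplitude is max − min of
  12 estimated monthly components; with ~2 RSV monthly noise over 16
  years each component carries se ≈ 0.5 RSV, and the max − min of 12
  such estimates is upward-biased by ~0.4–0.5 RSV. For seasonal swings
  below ~6 RSV this exceeds 10% relative error — the smallest-amplitude
  fixture topic (swing 4.5 RSV) recovers at about +11% for exactly this
  reason, which is an information limit of the estimator at that
  signal-to-noise, not an artefact of the implementation.
* The Seasonal Mann–Kendall test assumes independent seasons; strongly
  autocorrelated series inflate its size (Sen's slope, prewhitening and
  the inter-season covariance correction are documented non-goals).
* `tau` uses the tie-unadjusted denominator; with heavy censoring
  (many tied 0.5 values) printed tau values are comparable only within
  this convention.
* Region-share imputation applies the time-series rule (0 → 0.1,
  `<1` → 0.5) to shares; exports that never print `0` in region tables
  make this a no-op, but the assumption is surfaced in metadata.
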