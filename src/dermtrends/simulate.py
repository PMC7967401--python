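"""Synthetic Google-Trends-like data with known ground truth.

The study's raw inputs are live Google Trends exports, which cannot be
redistributed or regenerated deterministically.  This module provides a
latent search-intensity model and the observation transform Google
Trends applies to it, so every pipeline stage can be exercised against
known truth:

* latent model per topic: baseline level scaled by a popularity ratio
  relative to the benchmark topic, a linear secular trend, a 12-month
  seasonal pattern, an extra December dip (search activity drops over
  the holidays), and additive Gaussian noise clipped to stay positive;
* observation transform: max-100 rescaling (alone or jointly for a
  pairwise query), integer rounding, the "<1" censoring token, zero for
  no interest, per-country share tables summing to 100, and masking of
  countries below a search-volume threshold.

The "paper-like" world fixture mirrors the qualitative structure of the
observed data: 34 skin-sign topics with popularity ratios spanning
0.01-2.21, secular growth for every topic, warm-month peaks and December
troughs for most, one aseasonal topic (hair loss), and a handful of
low-volume countries that the exclusion rule should drop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gt_io import (
    CENSORED,
    RegionShareTable,
    TopicSeries,
    format_region_csv,
    format_series_csv,
)
from .registry import Registry, default_registry

EPS = 0.001  # positivity floor for latent intensity


@dataclass
class LatentTopicModel:
    """Ground-truth generating model for one topic's latent search intensity.

    ``x_t = max(eps, baseline * popularity_ratio + slope * t/12
    + monthly_pattern[month(t)] + december_dip * 1[month = Dec]
    + N(0, noise_sd^2))``
    """

    topic_id: str
    baseline: float
    slope: float  # latent units per year
    monthly_pattern: np.ndarray  # 12 values, January..December, sum ~ 0
    december_dip: float = 0.0
    noise_sd: float = 0.0
    popularity_ratio: float = 1.0

    def __post_init__(self) -> None:
        self.monthly_pattern = np.asarray(self.monthly_pattern, dtype=float)
        if self.monthly_pattern.shape != (12,):
            raise ValueError("monthly_pattern must have 12 entries")
        if abs(self.monthly_pattern.sum()) > 1e-6:
            raise ValueError("monthly_pattern must sum to 0")
        if self.december_dip > 0:
            raise ValueError("december_dip must be <= 0")
        if self.baseline <= 0 or self.popularity_ratio <= 0 or self.noise_sd < 0:
            raise ValueError("baseline and popularity_ratio must be positive")
        worst = (
            self.baseline * self.popularity_ratio
            + float(self.monthly_pattern.min())
            + self.december_dip
            + min(0.0, self.slope * 16)
        )
        if worst <= 0:
            raise ValueError(
                f"{self.topic_id}: latent intensity can go non-positive (worst case {worst:.3f})"
            )

    def effective_monthly_component(self) -> np.ndarray:
        """Seasonal + December-dip effect per calendar month, centred."""
        comp = self.monthly_pattern.copy()
        comp[11] += self.december_dip
        return comp - comp.mean()

    def noise_free(self, months: pd.PeriodIndex) -> np.ndarray:
        t = np.arange(len(months), dtype=float)
        m = np.asarray(months.month) - 1
        x = (
            self.baseline * self.popularity_ratio
            + self.slope * t / 12.0
            + self.monthly_pattern[m]
            + np.where(m == 11, self.december_dip, 0.0)
        )
        return np.maximum(EPS, x)

    def mean_intensity(self, months: pd.PeriodIndex) -> float:
        """Exact noise-free mean over the window (the true popularity level)."""
        return float(self.noise_free(months).mean())


@dataclass
class LatentWorld:
    """Complete ground truth: topic models, country weights, months, seed."""

    topics: dict[str, LatentTopicModel]
    reference_id: str
    months: pd.PeriodIndex
    seed: int
    # country -> (per-topic latent weight, total search volume)
    country_weights: dict[str, dict[str, float]] = field(default_factory=dict)
    country_volume: dict[str, float] = field(default_factory=dict)
    masking_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.reference_id not in self.topics:
            raise ValueError("reference topic missing from world")
        for c, v in self.country_volume.items():
            if v <= 0:
                raise ValueError(f"non-positive search volume for {c}")

    @property
    def countries(self) -> list[str]:
        return list(self.country_weights)

    def masked_countries(self) -> list[str]:
        return [c for c in self.countries if self.country_volume[c] < self.masking_threshold]

    def true_mean_ratio(self, topic_id: str) -> float:
        """Exact noise-free ratio of mean intensities, topic vs reference."""
        return self.topics[topic_id].mean_intensity(self.months) / self.topics[
            self.reference_id
        ].mean_intensity(self.months)


def simulate_latent(
    m: LatentTopicModel, months: pd.PeriodIndex, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw one latent series; bit-identical for identical seeds."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = m.noise_free(months)
    if m.noise_sd > 0:
        x = x + rng.normal(0.0, m.noise_sd, size=len(months))
    return np.maximum(EPS, x)


def _tokenize(scaled: np.ndarray, original: np.ndarray) -> list[object]:
    tokens: list[object] = []
    for s, x in zip(scaled, original):
        if x == 0:
            tokens.append(0)
            continue
        r = int(np.rint(s))
        tokens.append(r if r >= 1 else CENSORED)
    return tokens


def gt_transform_single(latent: np.ndarray) -> tuple[list[object], float]:
    """Max-100 rescale + integer rounding + censoring for one series.

    Returns the raw token list and the applied scale factor (100/max),
    which downstream recovery tests need to express latent truth in RSV
    units.  Scale-invariant: multiplying the latent series by any c > 0
    leaves the tokens unchanged.
    """
    x = np.asarray(latent, dtype=float)
    if np.any(x < 0):
        raise ValueError("latent series must be non-negative")
    peak = x.max()
    if peak == 0:
        raise ValueError("all-zero series would be masked by Google Trends")
    scale = 100.0 / peak
    return _tokenize(x * scale, x), scale


def gt_transform_pairwise(
    latent_a: np.ndarray, latent_b: np.ndarray
) -> tuple[list[object], list[object], float]:
    """Joint max-100 rescale of two series from one compared query."""
    a = np.asarray(latent_a, dtype=float)
    b = np.asarray(latent_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("pairwise series must share months")
    peak = max(a.max(), b.max())
    if peak == 0:
        raise ValueError("both series all-zero; Google Trends would mask the query")
    scale = 100.0 / peak
    return _tokenize(a * scale, a), _tokenize(b * scale, b), scale


def simulate_region_breakdown(
    w: LatentWorld, topic_id: str, reference_id: str | None = None
) -> tuple[RegionShareTable, dict[str, float]]:
    """Per-country share table of a topic vs the reference, plus true shares.

    Per country the latent interest is weight / total_volume (interest is
    per Google user, not crude volume); shares are the rounded split of
    100 between the two topics.  Countries below the masking threshold
    emit masked rows, as Google Trends does for low search volume.
    """
    reference_id = reference_id or w.reference_id
    shares: dict[str, tuple[object, object] | None] = {}
    truth: dict[str, float] = {}
    for c in w.countries:
        if w.country_volume[c] < w.masking_threshold:
            shares[c] = None
            continue
        i_t = w.country_weights[c].get(topic_id, 0.0) / w.country_volume[c]
        i_r = w.country_weights[c].get(reference_id, 0.0) / w.country_volume[c]
        if i_t + i_r == 0:
            shares[c] = None
            continue
        true_share = 100.0 * i_t / (i_t + i_r)
        truth[c] = true_share
        s_t = int(np.rint(true_share))
        shares[c] = (s_t, 100 - s_t)
    return (
        RegionShareTable(topic_id=topic_id, reference_id=reference_id, shares=shares),
        truth,
    )


def nonadjusted_region_values(w: LatentWorld) -> dict[str, dict[str, float]]:
    """Single-topic per-country RSV (0-100 integers) for the exclusion rule.

    Each topic column is scaled so the country with the highest per-user
    interest reads 100; values rounding below 1 read 0.  Masked countries
    carry 0 for every topic.
    """
    out: dict[str, dict[str, float]] = {c: {} for c in w.countries}
    masked = set(w.masked_countries())
    for tid in w.topics:
        interest = {
            c: (0.0 if c in masked else w.country_weights[c].get(tid, 0.0) / w.country_volume[c])
            for c in w.countries
        }
        peak = max(interest.values())
        for c in w.countries:
            out[c][tid] = 0 if peak == 0 else int(np.rint(100.0 * interest[c] / peak))
    return out


def _series(tid: str, months: pd.PeriodIndex, tokens: list[object], region="world") -> TopicSeries:
    return TopicSeries(
        topic_id=tid, region=region, months=months, values=np.array(tokens, dtype=object)
    )


def simulate_pairwise_series(
    w: LatentWorld, topic_id: str, seed_offset: int = 0
) -> tuple[TopicSeries, TopicSeries, float]:
    """Raw jointly-scaled (topic, reference) series for one compared query."""
    rng = _rng_for(w, topic_id, purpose=1 + seed_offset)
    a = simulate_latent(w.topics[topic_id], w.months, rng)
    b = simulate_latent(w.topics[w.reference_id], w.months, rng)
    tok_a, tok_b, scale = gt_transform_pairwise(a, b)
    return (
        _series(topic_id, w.months, tok_a),
        _series(w.reference_id, w.months, tok_b),
        scale,
    )


def simulate_single_series(
    w: LatentWorld, topic_id: str, seed_offset: int = 0
) -> tuple[TopicSeries, float]:
    """Raw self-scaled series for one single-topic (non-adjusted) query."""
    rng = _rng_for(w, topic_id, purpose=2 + seed_offset)
    x = simulate_latent(w.topics[topic_id], w.months, rng)
    tokens, scale = gt_transform_single(x)
    return _series(topic_id, w.months, tokens), scale


def _rng_for(w: LatentWorld, topic_id: str, purpose: int) -> np.random.Generator:
    idx = list(w.topics).index(topic_id)
    return np.random.default_rng(np.random.SeedSequence([w.seed, idx, purpose]))


# ---------------------------------------------------------------------------
# World fixtures

# (popularity ratio vs reference, secular slope, peak month index 0=Jan or
# None for the aseasonal topic, seasonal swing) per topic; ratios span the
# observed 0.01-2.21 range, every topic grows, most peak in warm months
# with a December trough, hair loss carries no seasonal term.
PAPER_LIKE_PARAMS: dict[str, tuple[float, float, int | None, float]] = {
    "itch": (2.21, 4.83, 6, 8.52),
    "hair_loss": (1.56, 1.34, None, 0.0),
    "skin_rash": (1.38, 3.34, 6, 13.92),
    "perspiration": (1.32, 2.85, 6, 22.01),
    "scar": (1.00, 3.63, 6, 9.91),
    "wart": (0.85, 2.42, 6, 22.87),
    "blister": (0.56, 3.37, 6, 24.99),
    "hives": (0.54, 2.03, 6, 11.39),
    "cellulite": (0.50, 1.15, 4, 43.77),
    "stretch_marks": (0.47, 2.52, 6, 23.24),
    "comedo": (0.46, 5.15, 7, 5.77),
    "skin_ulcer": (0.46, 3.21, 9, 4.50),
    "eczema": (0.43, 2.50, 4, 12.94),
    "nevus": (0.38, 4.17, 6, 9.89),
    "nodule": (0.38, 3.78, 4, 8.19),
    "dandruff": (0.37, 4.66, 0, 16.68),
    "xeroderma": (0.33, 4.02, 0, 19.11),
    "melanocytic_nevus": (0.32, 2.73, 6, 23.97),
    "erythema": (0.28, 1.57, 6, 14.78),
    "freckle": (0.26, 3.36, 5, 13.07),
    "papilloma": (0.22, 2.15, 9, 18.33),
    "melasma": (0.18, 4.62, 6, 14.21),
    "skin_tag": (0.13, 3.94, 7, 14.47),
    "papule": (0.09, 1.09, 6, 9.40),
    "vesicle": (0.08, 1.06, 9, 31.49),
    "hyperpigmentation": (0.07, 3.39, 5, 18.02),
    "telangiectasia": (0.07, 0.96, 5, 30.30),
    "liver_spots": (0.06, 1.47, 6, 33.35),
    "petechia": (0.06, 2.15, 4, 19.63),
    "abrasion": (0.05, 2.83, 5, 17.54),
    "pustule": (0.05, 3.89, 6, 13.03),
    "eschar": (0.04, 1.70, 5, 6.45),
    "skin_fissure": (0.02, 3.46, 11, 19.07),
    "cafe_au_lait_spot": (0.01, 0.47, 6, 20.67),
}

_BASELINE = 20.0
_DIP_FRACTION = 0.2  # December dip as a fraction of the seasonal swing
_NOISE_FRACTION = 0.02  # noise sd as a fraction of the latent peak
_SHARPNESS = 0.4  # 2nd-harmonic weight: summer peaks are peaked, not sinusoidal
_ASYMMETRY = 0.2  # 1st-harmonic sine: interest ramps up and decays asymmetrically

_COUNTRIES = [
    "US", "GB", "DE", "FR", "IT", "ES", "PL", "NL", "BE", "SE",
    "NO", "DK", "FI", "PT", "GR", "CZ", "HU", "RO", "BG", "HR",
    "RS", "SK", "SI", "AT", "CH", "IE", "UA", "TR", "RU", "IN",
    "PK", "BD", "ID", "MY", "PH", "TH", "VN", "SG", "JP", "KR",
    "CN", "TW", "HK", "AU", "NZ", "ZA", "NG", "KE", "EG", "MA",
    "BR", "AR", "CL", "CO", "PE", "MX", "CA", "VE", "EC", "UY",
    "SA", "AE", "IL", "IR", "IQ", "QA", "KW", "OM", "LK", "NP",
    "IS", "MT",
]


def _seasonal_shape(peak_month: int, swing: float) -> np.ndarray:
    """Centred 12-month pattern with a sharp, slightly asymmetric peak.

    A fundamental cosine plus a second harmonic (peaked summers) and a
    small sine term (asymmetric rise/decay), normalized to the requested
    max-min swing with the peak at the requested calendar month.
    """
    m = np.arange(12)
    x = 2.0 * np.pi * (m - peak_month) / 12.0
    raw = np.cos(x) + _SHARPNESS * np.cos(2.0 * x) + _ASYMMETRY * np.sin(x)
    raw = raw - raw.mean()
    return swing * raw / (raw.max() - raw.min())


def make_world_fixture(preset: str, seed: int, registry: Registry | None = None) -> LatentWorld:
    """Deterministic LatentWorld fixtures.

    * ``paper-like``: 34 topics with the observed popularity-ratio span,
      positive secular slopes, warm-month peaks / December troughs, one
      aseasonal topic, 72 countries of which ~10% mask for low volume and
      a few fail the five-positive-topics rule.
    * ``null``: no trend, no seasonality, pure noise (calibration runs).
    * ``southern``: paper-like with seasonal patterns shifted 6 months.
    """
    if preset not in ("paper-like", "null", "southern"):
        raise ValueError(f"unknown preset: {preset!r}")
    registry = registry or default_registry()
    months = registry.months
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD0]))

    topics: dict[str, LatentTopicModel] = {}
    for t in registry.topics:
        ratio, slope_shape, peak, swing = PAPER_LIKE_PARAMS[t.id]
        if preset == "null":
            topics[t.id] = LatentTopicModel(
                topic_id=t.id,
                baseline=50.0,
                slope=0.0,
                monthly_pattern=np.zeros(12),
                december_dip=0.0,
                noise_sd=2.0,
                popularity_ratio=1.0,
            )
            continue
        if preset == "southern" and peak is not None:
            peak = (peak + 6) % 12
        # latent swing chosen so the observed (max-100-rescaled) seasonal
        # amplitude lands near the RSV-scale target `swing`
        swing_latent = swing * (_BASELINE + 16.0 * slope_shape) / max(1.0, 100.0 - swing / 2.0)
        pattern = (
            np.zeros(12) if peak is None else _seasonal_shape(peak, swing_latent)
        )
        # search activity drops over the holidays, unless the topic itself
        # peaks in December
        dip = -_DIP_FRACTION * swing_latent if peak not in (None, 11) else 0.0
        peak_shape = _BASELINE + slope_shape * 16.0 + swing_latent / 2.0
        # scale trend/seasonal/noise with the ratio so the whole latent
        # series is proportional to it and mean ratios stay comparable
        topics[t.id] = LatentTopicModel(
            topic_id=t.id,
            baseline=_BASELINE,
            slope=ratio * slope_shape,
            monthly_pattern=ratio * pattern,
            december_dip=ratio * dip,
            noise_sd=_NOISE_FRACTION * ratio * peak_shape,
            popularity_ratio=ratio,
        )

    # country structure
    if preset == "null":
        countries = _COUNTRIES[:10]
        weights = {c: {tid: 1.0 for tid in topics} for c in countries}
        volume = {c: 1.0 for c in countries}
        threshold = 0.0
    else:
        countries = list(_COUNTRIES)
        weights = {}
        volume = {}
        sparse = set(countries[-6:-1])  # 5 countries failing the 5-topic rule
        ratios = {tid: PAPER_LIKE_PARAMS[tid][0] for tid in topics}
        for c in countries:
            base = float(rng.lognormal(0.0, 0.5))
            w = {}
            for tid in topics:
                jitter = float(rng.lognormal(0.0, 0.4))
                w[tid] = ratios[tid] * base * jitter
            if c in sparse:
                keep = set(list(topics)[:3])
                w = {tid: (w[tid] * 1e-6 if tid not in keep else w[tid]) for tid in w}
            weights[c] = w
            volume[c] = float(rng.lognormal(1.0, 1.0))
        threshold = float(np.quantile(sorted(volume.values()), 0.10))

    return LatentWorld(
        topics=topics,
        reference_id=registry.reference.id,
        months=months,
        seed=seed,
        country_weights=weights,
        country_volume=volume,
        masking_threshold=threshold,
    )


def ground_truth_dict(w: LatentWorld) -> dict:
    """JSON-serializable ground truth for recovery tests and audits."""
    gt: dict = {
        "seed": w.seed,
        "reference": w.reference_id,
        "masking_threshold": w.masking_threshold,
        "masked_countries": w.masked_countries(),
        "topics": {},
    }
    for tid, m in w.topics.items():
        comp = m.effective_monthly_component()
        gt["topics"][tid] = {
            "popularity_ratio": m.popularity_ratio,
            "mean_ratio": w.true_mean_ratio(tid),
            "latent_slope_per_year": m.slope,
            "monthly_component": comp.tolist(),
            "amplitude_latent": float(comp.max() - comp.min()),
            "noise_sd": m.noise_sd,
        }
    return gt


def write_world(w: LatentWorld, out_dir: str | Path) -> Path:
    """Materialize a world as Google-Trends-dialect CSVs plus ground truth.

    Layout: ``pairwise_<topic>.csv`` (topic vs reference, jointly scaled
    interest over time), ``single_<topic>.csv`` (self-scaled interest over
    time), ``region_<topic>.csv`` (compared breakdown by region),
    ``region_nonadjusted.csv`` (per-topic single-query region RSV used by
    the exclusion rule) and ``ground_truth.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = ground_truth_dict(w)
    truth["scales"] = {"pairwise": {}, "single": {}}
    truth["region_true_shares"] = {}

    for tid in w.topics:
        single, scale_s = simulate_single_series(w, tid)
        (out / f"single_{tid}.csv").write_text(format_series_csv([single]))
        truth["scales"]["single"][tid] = scale_s
        if tid != w.reference_id:
            a, b, scale_p = simulate_pairwise_series(w, tid)
            (out / f"pairwise_{tid}.csv").write_text(format_series_csv([a, b]))
            truth["scales"]["pairwise"][tid] = scale_p
            table, true_shares = simulate_region_breakdown(w, tid)
            (out / f"region_{tid}.csv").write_text(format_region_csv(table))
            truth["region_true_shares"][tid] = true_shares

    region_vals = nonadjusted_region_values(w)
    tids = list(w.topics)
    lines = ["Country," + ",".join(tids)]
    for c in w.countries:
        lines.append(c + "," + ",".join(str(int(region_vals[c][tid])) for tid in tids))
    (out / "region_nonadjusted.csv").write_text("\n".join(lines) + "\n")
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return out
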