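"""End-to-end orchestration of the search-interest analysis.

Consumes a directory of Google-Trends-dialect CSVs (real exports or the
simulator's output) and produces the three result tables of the study
design:

* a global popularity table — each topic's mean RSV as a proportion of
  the reference topic (reference pinned at 1.00), sorted descending;
* a per-topic time-series table — Seasonal Mann-Kendall statistics,
  OLS slope in RSV/year (reported only when the trend is significant),
  seasonality flag from the harmonic F-test, peak/trough months of the
  seasonal component and the yearly amplitude;
* a per-country winner table — each included country's topic ranking
  under 50-anchored region shares, with low-search-volume countries
  excluded.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .anchoring import (
    PairwiseComparison,
    adjusted_proportion,
    anchor_region,
    exclude_low_volume,
    rank_topics_by_country,
)
from .gt_io import (
    CENSORED_VALUE,
    ZERO_VALUE,
    impute_censored,
    impute_shares,
    parse_interest_by_region,
    parse_interest_over_time,
    write_table,
)
from .registry import Registry, default_registry
from .seasonality import stl_periodic
from .trend import seasonal_mann_kendall

log = logging.getLogger("dermtrends")


@dataclass
class AnalysisConfig:
    input_dir: Path
    output_dir: Path
    reference: str = "scar"
    period: int = 12
    alpha: float = 0.05
    min_topics: int = 5
    precision: int = 2
    registry: Registry = field(default_factory=default_registry)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        reg = default_registry()
        if "registry" in raw:
            from . import registry as _registry

            reg = _registry.from_config(raw["registry"])
        return cls(
            input_dir=raw["input_dir"],
            output_dir=raw["output_dir"],
            reference=raw.get("reference", "scar"),
            period=int(raw.get("period", 12)),
            alpha=float(raw.get("alpha", 0.05)),
            min_topics=int(raw.get("min_topics", 5)),
            precision=int(raw.get("precision", 2)),
            registry=reg,
            seed=raw.get("seed"),
        )


def _read(path: Path) -> str:
    return path.read_text(encoding="utf-8")


def run_pipeline(cfg: AnalysisConfig) -> dict:
    """Run the full analysis; returns tables and writes CSV/JSON outputs."""
    t0 = time.time()
    if not cfg.input_dir.is_dir():
        raise FileNotFoundError(f"input directory not found: {cfg.input_dir}")
    reg = cfg.registry
    ref_id = cfg.reference
    topic_ids = [t.id for t in reg.topics]

    # --- global proportions (time mode) -----------------------------------
    rows = [{"topic": ref_id, "proportion": 1.00}]
    for tid in topic_ids:
        if tid == ref_id:
            continue
        path = cfg.input_dir / f"pairwise_{tid}.csv"
        if not path.exists():
            raise FileNotFoundError(
                f"missing reference comparison for topic {tid!r}: {path.name}"
            )
        series = parse_interest_over_time(_read(path))
        by_id = {s.topic_id: s for s in series}
        if ref_id not in by_id:
            raise ValueError(f"{path.name}: no column for reference topic {ref_id!r}")
        topic_series = next(s for s in series if s.topic_id != ref_id)
        comp = PairwiseComparison(
            topic=impute_censored(topic_series),
            reference=impute_censored(by_id[ref_id]),
        )
        rows.append({"topic": tid, "proportion": adjusted_proportion(comp).value})
    proportion_table = (
        pd.DataFrame(rows)
        .sort_values(["proportion", "topic"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    log.info("proportions: %d topics in %.2fs", len(proportion_table), time.time() - t0)

    # --- per-topic secular trend and seasonality --------------------------
    trend_rows = []
    for tid in topic_ids:
        t_topic = time.time()
        path = cfg.input_dir / f"single_{tid}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing single-topic series for {tid!r}")
        s = impute_censored(parse_interest_over_time(_read(path))[0])
        tr = seasonal_mann_kendall(s, period=cfg.period, alpha=cfg.alpha)
        dec = stl_periodic(s, period=cfg.period, alpha=cfg.alpha)
        significant = tr.p_two_sided < cfg.alpha
        trend_rows.append(
            {
                "topic": tid,
                "S": tr.S,
                "varS": tr.var_S,
                "Z": tr.Z,
                "tau": tr.tau,
                "p": tr.p_two_sided,
                "stars": tr.stars,
                "slope": tr.slope if significant else float("nan"),
                "slope_note": "" if significant else "n/a (no significant trend)",
                "slope_p": tr.slope_p if significant else float("nan"),
                "seasonal": bool(dec.seasonal_present),
                "seasonal_p": dec.seasonal_p,
                "peak_month": dec.peak_month if dec.seasonal_present else "-",
                "peak_value": dec.monthly_component.max() if dec.seasonal_present else float("nan"),
                "trough_month": dec.trough_month if dec.seasonal_present else "-",
                "trough_value": dec.monthly_component.min() if dec.seasonal_present else float("nan"),
                "amplitude": dec.amplitude if dec.seasonal_present else float("nan"),
            }
        )
        log.debug("trend %s: %.2fs", tid, time.time() - t_topic)
    trend_table = pd.DataFrame(trend_rows)
    log.info("trend/seasonality: %d topics in %.2fs", len(trend_table), time.time() - t0)

    # --- per-country rankings ---------------------------------------------
    nonadj_path = cfg.input_dir / "region_nonadjusted.csv"
    excluded: set[str] = set()
    if nonadj_path.exists():
        df = pd.read_csv(nonadj_path)
        values = {
            str(r["Country"]): {c: r[c] for c in df.columns if c != "Country"}
            for _, r in df.iterrows()
        }
        excluded = exclude_low_volume(values, min_topics=cfg.min_topics)

    anchored: dict[str, dict[str, float]] = {}
    masked: dict[str, str] = {}
    for tid in topic_ids:
        if tid == ref_id:
            continue
        path = cfg.input_dir / f"region_{tid}.csv"
        if not path.exists():
            continue
        table = impute_shares(parse_interest_by_region(_read(path)))
        values_list, omitted = anchor_region(table)
        masked.update(omitted)
        for ap in values_list:
            anchored.setdefault(ap.scope, {})[tid] = ap.value
    for country in masked:
        anchored.pop(country, None)
    rankings = rank_topics_by_country(anchored, excluded, reg)
    country_rows = []
    for r in rankings:
        country_rows.append(
            {
                "country": r.country,
                "winner": r.winner or "",
                "top5": ";".join(r.ordering[:5]),
                "excluded": r.excluded,
                "reason": r.reason or ";".join(r.flags),
            }
        )
    for country, reason in sorted(masked.items()):
        country_rows.append(
            {"country": country, "winner": "", "top5": "", "excluded": True, "reason": reason}
        )
    country_table = pd.DataFrame(country_rows)

    metadata = {
        "version": __version__,
        "config": {
            "reference": ref_id,
            "period": cfg.period,
            "alpha": cfg.alpha,
            "min_topics": cfg.min_topics,
            "seed": cfg.seed,
        },
        "decisions": {
            "imputation": f"'<1' -> {CENSORED_VALUE}; '0' -> {ZERO_VALUE}; applied to time series and region shares",
            "proportion": "ratio of mean imputed RSV over the full period",
            "seasonality_test": "harmonic-regression F-test (2 Fourier harmonics of the annual cycle) in place of a TBATS fit",
            "stars": "*** p<0.001, ** p<0.01, * p<0.05",
        },
        "counts": {
            "topics": len(topic_ids),
            "countries_total": int(country_table.shape[0]),
            "countries_excluded": int(country_table["excluded"].sum()) if len(country_table) else 0,
        },
        "runtime_s": round(time.time() - t0, 2),
    }

    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    for name, table in (
        ("proportions", proportion_table),
        ("trend", trend_table),
        ("countries", country_table),
    ):
        write_table(table, cfg.output_dir / f"{name}.csv", "csv", report_mode=True)
        write_table(table, cfg.output_dir / f"{name}.json", "json")
    winners = render_country_winners(country_table)
    write_table(winners, cfg.output_dir / "winners.csv", "csv")
    (cfg.output_dir / "metadata.json").write_text(json.dumps(metadata, indent=1))
    log.info("pipeline done in %.2fs", time.time() - t0)
    return {
        "proportion_table": proportion_table,
        "trend_table": trend_table,
        "country_table": country_table,
        "metadata": metadata,
    }


def render_country_winners(country_table: pd.DataFrame) -> pd.DataFrame:
    """Two-column (country, winner) export for external choropleth tools.

    Excluded countries are dropped from the export; the caller's country
    table keeps them with their exclusion reason as the audit sidecar.
    """
    if country_table.empty:
        raise ValueError("country table is empty")
    kept = country_table[~country_table["excluded"]]
    return kept[["country", "winner"]].reset_index(drop=True)
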