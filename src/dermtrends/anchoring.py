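"""Benchmark anchoring: one popularity scale via pairwise reference comparisons.

Google Trends only reports *relative* search volume within one query set,
so cross-topic comparison requires a common benchmark.  Every topic is
compared pairwise against the reference topic; the ratio of mean RSVs
places it on a single scale where the reference is 1.00 (global time
mode) or 50 (per-country region mode).  Countries where fewer than five
topics register any search volume are excluded as unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .gt_io import CENSORED, RegionShareTable, TopicSeries, ZERO_VALUE
from .registry import Registry

#: anchored RSV assigned to the reference topic in every region
REGION_REFERENCE_VALUE = 50.0


@dataclass
class PairwiseComparison:
    """Two topic series from one joint Google Trends query."""

    topic: TopicSeries
    reference: TopicSeries
    jointly_scaled: bool = True

    def __post_init__(self) -> None:
        if not self.topic.months.equals(self.reference.months):
            raise ValueError("topic and reference series do not share months")
        if self.topic.region != self.reference.region:
            raise ValueError("topic and reference series differ in region")

    def validate_joint_scale(self) -> None:
        """A jointly scaled raw pair must peak at exactly 100 overall."""
        if not self.jointly_scaled:
            return
        numeric = [
            v
            for s in (self.topic, self.reference)
            for v in s.values
            if v != CENSORED
        ]
        if numeric and max(float(v) for v in numeric) != 100:
            raise ValueError("jointly scaled raw pair does not peak at 100")


@dataclass(frozen=True)
class AnchoredPopularity:
    topic_id: str
    scope: str  # "world-time" or a country name/code
    value: float


@dataclass
class CountryRanking:
    country: str
    ordering: list[str]  # topic ids, descending anchored value
    winner: str | None
    excluded: bool = False
    reason: str | None = None
    flags: list[str] = field(default_factory=list)


def adjusted_proportion(c: PairwiseComparison) -> AnchoredPopularity:
    """Global popularity of a topic as a proportion of the reference topic.

    Defined as the ratio of the mean imputed RSV of the topic to that of
    the reference over the whole study period; the reference against
    itself is exactly 1.00 by construction.
    """
    if not (c.topic.imputed and c.reference.imputed):
        raise ValueError("adjusted_proportion requires imputed series")
    if len(c.topic) < 12:
        raise ValueError("need at least 12 months for a stable proportion")
    if c.topic.topic_id == c.reference.topic_id:
        return AnchoredPopularity(c.topic.topic_id, "world-time", 1.0)
    ratio = float(c.topic.values.mean() / c.reference.values.mean())
    return AnchoredPopularity(c.topic.topic_id, "world-time", ratio)


def anchor_region(t: RegionShareTable) -> tuple[list[AnchoredPopularity], dict[str, str]]:
    """Per-country anchored RSV with the reference pinned at 50.

    For each unmasked country the anchored value is
    ``50 * share_topic / share_reference``; imputation guarantees the
    reference share is at least 0.1.  Returns the anchored values and a
    mapping of omitted countries to the reason ("masked").
    """
    if not t.imputed:
        raise ValueError("anchor_region requires an imputed share table")
    anchored: list[AnchoredPopularity] = []
    omitted: dict[str, str] = {}
    for country, pair in t.shares.items():
        if pair is None:
            omitted[country] = "masked"
            continue
        share_topic, share_ref = pair
        value = REGION_REFERENCE_VALUE * float(share_topic) / float(share_ref)
        anchored.append(AnchoredPopularity(t.topic_id, country, value))
    return anchored, omitted


def exclude_low_volume(
    nonadjusted_region_values: dict[str, dict[str, float]],
    min_topics: int = 5,
) -> set[str]:
    """Countries with fewer than ``min_topics`` topics of nonzero RSV.

    Operates on single-topic (non-adjusted) per-country RSV, where zero or
    missing means no measurable search volume.
    """
    excluded = set()
    for country, per_topic in nonadjusted_region_values.items():
        n_positive = sum(1 for v in per_topic.values() if v is not None and v > 0)
        if n_positive < min_topics:
            excluded.add(country)
    return excluded


def rank_topics_by_country(
    anchored: dict[str, dict[str, float]],
    excluded: set[str],
    registry: Registry,
) -> list[CountryRanking]:
    """Descending per-country topic ranking with deterministic tie-breaks.

    ``anchored`` maps country -> topic_id -> anchored value.  The
    reference topic participates at its fixed value of 50; topics missing
    for a country are scored as an imputed zero share (0.1 against a 100
    reference share, i.e. 0.05).  Ties break by registry order and are
    recorded; a country where every topic ties is flagged degenerate.
    """
    missing_value = REGION_REFERENCE_VALUE * ZERO_VALUE / 100.0
    rankings: list[CountryRanking] = []
    ref_id = registry.reference.id
    for country in sorted(anchored):
        if country in excluded:
            rankings.append(
                CountryRanking(country, [], None, excluded=True, reason="low search volume")
            )
            continue
        values = dict(anchored[country])
        values.setdefault(ref_id, REGION_REFERENCE_VALUE)
        for t in registry.topics:
            values.setdefault(t.id, missing_value)
        ordering = sorted(
            values, key=lambda tid: (-values[tid], registry.order(tid))
        )
        flags = []
        top = ordering[0]
        tied = [tid for tid in ordering if values[tid] == values[top]]
        if len(tied) > 1:
            flags.append("tie:" + ";".join(tied))
        if len(tied) == len(ordering):
            flags.append("degenerate")
        rankings.append(CountryRanking(country, ordering, top, flags=flags))
    return rankings
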