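"""Topic catalogue for the skin-sign search-interest study.

The study design compares every topic pairwise against a single benchmark
topic ("Scar") so that all topics can be placed on one popularity scale.
This module holds the canonical topic list (34 dermatologic clinical
signs, plus optional disease and non-medical control topics used in
sensitivity analyses), the reference flag, and the study period.
"""

from __future__ import annotations

import json
import unicodedata
from dataclasses import dataclass, field, replace

import pandas as pd
import yaml

CLINICAL_SIGN = "clinical_sign"
DISEASE_CONTROL = "disease_control"
NONMEDICAL_CONTROL = "nonmedical_control"

_CATEGORIES = frozenset({CLINICAL_SIGN, DISEASE_CONTROL, NONMEDICAL_CONTROL})

#: display names of the 34 clinical-sign topics; "Scar" is the benchmark.
CLINICAL_SIGN_NAMES = (
    "Abrasion", "Blister", "Café au lait spots", "Cellulite", "Comedo",
    "Dandruff", "Eczema", "Erythema", "Eschar", "Freckle", "Hair loss",
    "Hyperpigmentation", "Hives", "Itch", "Liver spots",
    "Melanocytic nevus", "Melasma", "Nevus", "Nodule", "Papilloma",
    "Papule", "Perspiration", "Petechia", "Pustule", "Scar",
    "Skin fissure", "Skin rash", "Skin tag", "Skin ulcer",
    "Stretch marks", "Telangiectasia", "Vesicle", "Wart", "Xeroderma",
)

DISEASE_CONTROL_NAMES = (
    "Atopic dermatitis", "Basal-cell carcinoma", "Melanoma", "Psoriasis",
    "Rosacea", "Scabies", "Squamous cell skin cancer",
)

NONMEDICAL_CONTROL_NAMES = (
    "Car", "FC Bayern Munich", "Rome", "Star Wars", "Tomato",
)

# ids that do not follow the plain slug of the display name
_ID_OVERRIDES = {
    "Café au lait spots": "cafe_au_lait_spot",
}


def slugify(name: str) -> str:
    """Lower-snake-case ASCII id for a topic display name."""
    if name in _ID_OVERRIDES:
        return _ID_OVERRIDES[name]
    ascii_name = (
        unicodedata.normalize("NFKD", name)
        .encode("ascii", "ignore")
        .decode("ascii")
    )
    out = []
    for ch in ascii_name.lower():
        if ch.isalnum():
            out.append(ch)
        elif out and out[-1] != "_":
            out.append("_")
    return "".join(out).strip("_")


@dataclass(frozen=True)
class Topic:
    id: str
    display_name: str
    category: str = CLINICAL_SIGN
    is_reference: bool = False

    def __post_init__(self) -> None:
        if self.category not in _CATEGORIES:
            raise ValueError(f"unknown topic category: {self.category!r}")


@dataclass(frozen=True)
class Registry:
    """Ordered topic collection with one reference topic and a study period."""

    topics: tuple[Topic, ...]
    period_start: pd.Period = field(default_factory=lambda: pd.Period("2004-01", "M"))
    period_end: pd.Period = field(default_factory=lambda: pd.Period("2019-12", "M"))

    @property
    def reference(self) -> Topic:
        refs = [t for t in self.topics if t.is_reference]
        if len(refs) != 1:
            raise ValueError(f"registry has {len(refs)} reference topics, expected 1")
        return refs[0]

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(t.id for t in self.topics)

    @property
    def months(self) -> pd.PeriodIndex:
        return pd.period_range(self.period_start, self.period_end, freq="M")

    def count(self, category: str | None = None) -> int:
        if category is None:
            return len(self.topics)
        return sum(1 for t in self.topics if t.category == category)

    def get(self, topic_id: str) -> Topic:
        for t in self.topics:
            if t.id == topic_id:
                return t
        raise KeyError(topic_id)

    def order(self, topic_id: str) -> int:
        """Registry position, used downstream as the deterministic tie-break."""
        for i, t in enumerate(self.topics):
            if t.id == topic_id:
                return i
        raise KeyError(topic_id)

    def subset(self, category: str) -> "Registry":
        return replace(self, topics=tuple(t for t in self.topics if t.category == category))


def default_registry(include_controls: bool = False) -> Registry:
    """The study's 34 clinical-sign topics, 'Scar' flagged as the benchmark.

    With ``include_controls=True`` the 7 skin-disease and 5 non-medical
    sensitivity-analysis topics are appended.
    """
    topics = [
        Topic(slugify(n), n, CLINICAL_SIGN, is_reference=(n == "Scar"))
        for n in CLINICAL_SIGN_NAMES
    ]
    if include_controls:
        topics += [Topic(slugify(n), n, DISEASE_CONTROL) for n in DISEASE_CONTROL_NAMES]
        topics += [Topic(slugify(n), n, NONMEDICAL_CONTROL) for n in NONMEDICAL_CONTROL_NAMES]
    return Registry(topics=tuple(topics))


def validate_registry(r: Registry) -> list[str]:
    """Collect invariant violations; empty list means the registry is valid."""
    violations: list[str] = []
    seen: set[str] = set()
    for t in r.topics:
        if not t.id:
            violations.append("topic with empty id")
        elif t.id in seen:
            violations.append(f"duplicate topic id: {t.id!r}")
        seen.add(t.id)
    n_ref = sum(1 for t in r.topics if t.is_reference)
    if n_ref == 0:
        violations.append("no topic flagged as reference")
    elif n_ref > 1:
        ids = [t.id for t in r.topics if t.is_reference]
        violations.append(f"multiple reference topics: {ids}")
    if r.period_end < r.period_start:
        violations.append("period_end precedes period_start")
    elif len(pd.period_range(r.period_start, r.period_end, freq="M")) % 12 != 0:
        violations.append("study period does not span a whole number of years")
    return violations


def to_config(r: Registry) -> dict:
    return {
        "topics": [
            {"id": t.id, "display_name": t.display_name, "category": t.category}
            for t in r.topics
        ],
        "reference": r.reference.id,
        "period": {"start": str(r.period_start), "end": str(r.period_end)},
    }


def from_config(cfg: dict) -> Registry:
    ref = cfg["reference"]
    topics = tuple(
        Topic(
            t["id"],
            t.get("display_name", t["id"]),
            t.get("category", CLINICAL_SIGN),
            is_reference=(t["id"] == ref),
        )
        for t in cfg["topics"]
    )
    period = cfg.get("period", {})
    return Registry(
        topics=topics,
        period_start=pd.Period(period.get("start", "2004-01"), "M"),
        period_end=pd.Period(period.get("end", "2019-12"), "M"),
    )


def dump(r: Registry, path, fmt: str = "yaml") -> None:
    cfg = to_config(r)
    with open(path, "w", encoding="utf-8") as fh:
        if fmt == "yaml":
            yaml.safe_dump(cfg, fh, sort_keys=False, allow_unicode=True)
        elif fmt == "json":
            json.dump(cfg, fh, ensure_ascii=False, indent=1)
        else:
            raise ValueError(f"unknown format: {fmt}")


def load(path) -> Registry:
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    cfg = yaml.safe_load(text)
    return from_config(cfg)
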