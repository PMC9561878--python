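"""Three-tier confidence classification of circle calls.

Tiers are nested: every high-confidence (hconf) call also satisfies the
conf predicate, and every conf call the lconf predicate.

* lconf — at least one supporting split read;
* conf  — lconf and sequencing coverage of the interval >= 80%;
* hconf — conf and a coverage step > 0.5 at both boundaries (the relative
  depth of the circle exceeding twice its surroundings).

Calls with zero split reads are unclassified and excluded from tier
summaries.  At cohort level a merged locus takes the best tier any single
sample achieved.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable

from eccatlas.io_formats import CircleCall, CircleCallTable

logger = logging.getLogger(__name__)


class ConfidenceTier(enum.IntEnum):
    """Ordered confidence tiers: lconf < conf < hconf."""

    LCONF = 1
    CONF = 2
    HCONF = 3

    @property
    def label(self) -> str:
        return {1: "lconf", 2: "conf", 3: "hconf"}[int(self)]

    @classmethod
    def from_label(cls, label: str) -> "ConfidenceTier":
        for member in cls:
            if member.label == label:
                return member
        raise ValueError(f"unknown tier label {label!r}")


@dataclass(frozen=True)
class ConfidenceRules:
    """Thresholds of the tier predicates (defaults are the standard rules).

    ``hconf_mode`` selects how the twice-average-depth criterion is read:
    ``edge_ratio`` (default) uses the boundary coverage-increase ratios
    > ``min_edge_ratio``; ``mean_depth`` would require an externally
    supplied genome-average depth and is intentionally not implemented by
    the classifier itself.
    """

    min_split: int = 1
    min_coverage_fraction: float = 0.80
    min_edge_ratio: float = 0.5
    hconf_mode: str = "edge_ratio"


def classify_confidence(call: CircleCall, rules: ConfidenceRules | None = None,
                        ) -> ConfidenceTier | None:
    """Assign a tier, or ``None`` when the call has no split support."""
    rules = rules or ConfidenceRules()
    if call.n_split < rules.min_split:
        return None
    if call.coverage_fraction >= rules.min_coverage_fraction:
        if (call.cov_increase_start > rules.min_edge_ratio
                and call.cov_increase_end > rules.min_edge_ratio):
            return ConfidenceTier.HCONF
        return ConfidenceTier.CONF
    return ConfidenceTier.LCONF


def summarize_tiers(calls: CircleCallTable | Iterable[CircleCall],
                    rules: ConfidenceRules | None = None) -> dict[str, int]:
    """Count classified calls per tier; unclassifiable calls are dropped."""
    rules = rules or ConfidenceRules()
    counts = Counter()
    n_unclassified = 0
    for call in calls:
        tier = classify_confidence(call, rules)
        if tier is None:
            n_unclassified += 1
        else:
            counts[tier.label] += 1
    if n_unclassified:
        logger.warning("%d calls without split support left unclassified",
                       n_unclassified)
    return {"hconf": counts["hconf"], "conf": counts["conf"],
            "lconf": counts["lconf"]}


def cohort_tier(calls: Iterable[CircleCall],
                rules: ConfidenceRules | None = None) -> ConfidenceTier:
    """Best tier achieved by any single sample's call at one merged locus."""
    rules = rules or ConfidenceRules()
    tiers = [t for t in (classify_confidence(c, rules) for c in calls)
             if t is not None]
    if not tiers:
        raise ValueError("no classifiable call at locus")
    return max(tiers)
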