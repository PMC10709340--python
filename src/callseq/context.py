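"""Feeding-context association via tail-slap proximity.

A transition event counts as produced in a feeding context when a
high-quality tail slap on the same tag lies within a symmetric window
(default 5 minutes) of the event time — the start of the first call of
the pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .markov import TransitionEvent
from .clusters import CombinationCluster
from .records import HIGH_QUALITY, ParameterError, TailSlapEvent

__all__ = [
    "LabeledEvent",
    "ClusterContext",
    "ContextSummary",
    "label_feeding",
    "context_summary",
]

DEFAULT_WINDOW_S = 300.0


@dataclass(frozen=True)
class LabeledEvent:
    event: TransitionEvent
    feeding: bool


@dataclass(frozen=True)
class ClusterContext:
    cluster_id: str
    n_feeding: int
    n_total: int
    proportion_feeding: float


@dataclass(frozen=True)
class ContextSummary:
    n_total: int
    n_feeding: int
    proportion_feeding: float
    proportion_non_feeding: float
    per_cluster: dict[str, ClusterContext] = field(default_factory=dict)


def label_feeding(
    events: Sequence[TransitionEvent],
    tail_slaps: Iterable[TailSlapEvent],
    window_s: float = DEFAULT_WINDOW_S,
    high_quality_only: bool = True,
) -> list[LabeledEvent]:
    """Label each event feeding iff a same-tag slap lies within the window.

    The window is symmetric (before or after a slap).  Tags without any
    slap yield all non-feeding labels.
    """
    if window_s <= 0:
        raise ParameterError(f"window_s must be positive, got {window_s}")
    slaps_by_tag: dict[str, list[float]] = {}
    for slap in tail_slaps:
        if high_quality_only and slap.quality != HIGH_QUALITY:
            continue
        slaps_by_tag.setdefault(slap.tag_id, []).append(slap.time_s)

    labeled = []
    for event in events:
        times = slaps_by_tag.get(event.tag_id, ())
        feeding = any(abs(event.time_s - t) <= window_s for t in times)
        labeled.append(LabeledEvent(event=event, feeding=feeding))
    return labeled


def context_summary(
    labeled: Sequence[LabeledEvent],
    clusters: Sequence[CombinationCluster] = (),
) -> ContextSummary:
    """Feeding proportions overall and per combination cluster.

    The overall proportion is computed over every labeled event (all
    gated transitions); per-cluster proportions use the cluster's own
    event count as denominator.  Clusters with no events are omitted.
    """
    n_total = len(labeled)
    n_feeding = sum(1 for item in labeled if item.feeding)

    edge_owner: dict[tuple[str, str], str] = {}
    for cluster in clusters:
        for pair in cluster.edge_pairs:
            edge_owner[pair] = cluster.cluster_id

    counts: dict[str, list[int]] = {c.cluster_id: [0, 0] for c in clusters}
    for item in labeled:
        owner = edge_owner.get((item.event.from_cat, item.event.to_cat))
        if owner is None:
            continue
        counts[owner][1] += 1
        if item.feeding:
            counts[owner][0] += 1

    per_cluster = {
        cid: ClusterContext(
            cluster_id=cid,
            n_feeding=feed,
            n_total=total,
            proportion_feeding=feed / total,
        )
        for cid, (feed, total) in counts.items()
        if total > 0
    }
    prop = n_feeding / n_total if n_total else float("nan")
    return ContextSummary(
        n_total=n_total,
        n_feeding=n_feeding,
        proportion_feeding=prop,
        proportion_non_feeding=1.0 - prop if n_total else float("nan"),
        per_cluster=per_cluster,
    )
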