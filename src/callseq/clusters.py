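"""Combination-cluster extraction and sequence validation.

A combination cluster is a weakly connected component of the directed
graph whose edges are significant over-expected *mixed* transitions
(different categories) observed more than ``min_count`` times.
Same-category repetitions are summarized separately: the repetition
share and the cluster share of gated transitions need not sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .markov import PosthocCell, TransitionEvent, TransitionTable
from .records import CallRecord, UndefinedShareError, check_sorted

__all__ = [
    "CombinationCluster",
    "ValidatedSequence",
    "ShareSummary",
    "extract_clusters",
    "validate_sequences",
    "summarize_shares",
]


@dataclass(frozen=True)
class CombinationCluster:
    cluster_id: str
    categories: frozenset[str]
    #: (from_cat, to_cat, observed count); no self-loops
    edges: tuple[tuple[str, str, int], ...]
    n_transitions: int

    @property
    def edge_pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset((a, b) for a, b, _ in self.edges)


@dataclass(frozen=True)
class ValidatedSequence:
    tag_id: str
    call_ids: tuple[str, ...]
    categories: tuple[str, ...]
    length: int
    cluster_id: Optional[str]
    start_s: float


@dataclass(frozen=True)
class ShareSummary:
    n_total: int
    n_repetition: int
    repetition_share: float
    n_cluster: int
    cluster_share: float
    per_cluster: dict[str, int] = field(default_factory=dict)


def extract_clusters(
    cells: Iterable[PosthocCell], min_count: int = 10
) -> list[CombinationCluster]:
    """Weakly connected components of significant mixed transitions.

    Edges: cells flagged ``significant_over`` with different from/to
    categories and observed count strictly greater than ``min_count``.
    Clusters are ordered by descending total transition count, ties
    broken by the lexicographically smallest member, and labelled
    ``cluster_1``, ``cluster_2``, ...
    """
    graph = nx.DiGraph()
    for cell in cells:
        if cell.significant_over and cell.from_cat != cell.to_cat \
                and cell.observed > min_count:
            graph.add_edge(cell.from_cat, cell.to_cat, count=cell.observed)

    raw = []
    for component in nx.weakly_connected_components(graph):
        if len(component) < 2:
            continue
        sub = graph.subgraph(component)
        edges = tuple(
            sorted((a, b, d["count"]) for a, b, d in sub.edges(data=True))
        )
        total = sum(c for _, _, c in edges)
        raw.append((frozenset(component), edges, total))

    raw.sort(key=lambda item: (-item[2], min(item[0])))
    return [
        CombinationCluster(
            cluster_id=f"cluster_{i + 1}",
            categories=cats,
            edges=edges,
            n_transitions=total,
        )
        for i, (cats, edges, total) in enumerate(raw)
    ]


def _pair_set(significant_pairs) -> frozenset[tuple[str, str]]:
    pairs = set()
    for item in significant_pairs:
        if isinstance(item, PosthocCell):
            if item.significant_over:
                pairs.add((item.from_cat, item.to_cat))
        else:
            a, b = item
            pairs.add((str(a), str(b)))
    return frozenset(pairs)


def validate_sequences(
    calls_by_tag: Mapping[str, Sequence[CallRecord]],
    bci_s: float,
    significant_pairs: Iterable,
    clusters: Sequence[CombinationCluster] = (),
    exclude_variable: bool = True,
) -> list[ValidatedSequence]:
    """Maximal runs whose every adjacent pair is gated and significant.

    A run qualifies when each consecutive pair of retained calls lies
    within the bout criterion AND forms a significant over-expected
    transition.  Assembly is greedy-maximal left to right, so an
    embedded longer run is reported once.  Runs containing at least one
    mixed-category edge are assigned to the cluster holding those edges;
    pure-repetition runs carry ``cluster_id=None``.

    ``significant_pairs`` may be posthoc cells (their ``significant_over``
    flag is honoured) or explicit ``(from_cat, to_cat)`` pairs.
    """
    pairs = _pair_set(significant_pairs)
    by_edge: dict[tuple[str, str], str] = {}
    for cluster in clusters:
        for pair in cluster.edge_pairs:
            by_edge[pair] = cluster.cluster_id

    sequences: list[ValidatedSequence] = []
    for tag_id, calls in calls_by_tag.items():
        calls = list(calls)
        check_sorted(calls)
        if exclude_variable:
            calls = [c for c in calls if not c.is_variable]
        i = 0
        while i < len(calls) - 1:
            run = [calls[i]]
            j = i
            while j < len(calls) - 1:
                a, b = calls[j], calls[j + 1]
                gap = max(0.0, b.start_s - a.end_s)
                if gap <= bci_s and (a.category, b.category) in pairs:
                    run.append(b)
                    j += 1
                else:
                    break
            if len(run) >= 2:
                mixed_clusters = {
                    by_edge[(a.category, b.category)]
                    for a, b in zip(run, run[1:])
                    if a.category != b.category
                    and (a.category, b.category) in by_edge
                }
                has_mixed = any(
                    a.category != b.category for a, b in zip(run, run[1:])
                )
                cluster_id = (
                    mixed_clusters.pop()
                    if has_mixed and len(mixed_clusters) == 1
                    else None
                )
                sequences.append(
                    ValidatedSequence(
                        tag_id=tag_id,
                        call_ids=tuple(c.call_id for c in run),
                        categories=tuple(c.category for c in run),
                        length=len(run),
                        cluster_id=cluster_id,
                        start_s=run[0].start_s,
                    )
                )
                i = j
            else:
                i += 1
    return sequences


def summarize_shares(
    events: Sequence[TransitionEvent] | TransitionTable,
    clusters: Sequence[CombinationCluster],
) -> ShareSummary:
    """Repetition and combination-cluster shares of the gated transitions.

    Repetitions are events whose two calls share a category; cluster
    transitions are events whose ordered pair is an edge of some
    cluster.  Shares are fractions of all gated events and need not sum
    to 1 (events may be neither).
    """
    if isinstance(events, TransitionTable):
        events = events.events
    n_total = len(events)
    if n_total == 0:
        raise UndefinedShareError("no gated transition events: shares undefined")

    n_repetition = sum(1 for e in events if e.from_cat == e.to_cat)
    per_cluster = {c.cluster_id: 0 for c in clusters}
    edge_owner: dict[tuple[str, str], str] = {}
    for cluster in clusters:
        for pair in cluster.edge_pairs:
            edge_owner[pair] = cluster.cluster_id
    n_cluster = 0
    for e in events:
        owner = edge_owner.get((e.from_cat, e.to_cat))
        if owner is not None:
            per_cluster[owner] += 1
            n_cluster += 1
    return ShareSummary(
        n_total=n_total,
        n_repetition=n_repetition,
        repetition_share=n_repetition / n_total,
        n_cluster=n_cluster,
        cluster_share=n_cluster / n_total,
        per_cluster=per_cluster,
    )
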