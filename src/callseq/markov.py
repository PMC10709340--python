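"""First-order transition analysis of bout-gated call sequences.

Transitions are ordered pairs of consecutive retained calls within the
same tag whose silent gap does not exceed the bout criterion interval.
The observed count matrix is tested against the independence null with a
Pearson chi-squared statistic whose p-value comes from Monte-Carlo
resampling of tables with both margins fixed (Patefield sampling).
Per-cell follow-up uses margin-adjusted standardized residuals with a
Bonferroni correction over all cells of the square table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .records import (
    CallRecord,
    ParameterError,
    DegenerateTableError,
    check_sorted,
)

log = logging.getLogger(__name__)

__all__ = [
    "TransitionEvent",
    "TransitionTable",
    "ChiSquareResult",
    "PosthocCell",
    "build_transitions",
    "expected_counts",
    "chi_square_mc",
    "posthoc_residuals",
    "filter_min_count",
    "possible_transition_count",
]


@dataclass(frozen=True)
class TransitionEvent:
    tag_id: str
    from_call_id: str
    to_call_id: str
    from_cat: str
    to_cat: str
    gap_s: float
    #: start time of the first call of the pair (context labelling anchor)
    time_s: float


@dataclass
class TransitionTable:
    """Square matrix of ordered category-pair counts plus the event list."""

    categories: list[str]
    counts: np.ndarray
    events: list[TransitionEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        c = len(self.categories)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (c, c):
            raise ParameterError(
                f"counts shape {self.counts.shape} does not match "
                f"{c} categories"
            )
        if np.any(self.counts < 0):
            raise ParameterError("counts must be non-negative")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def index(self, category: str) -> int:
        return self.categories.index(category)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    p_mc: float
    n_sim: int
    seed: Optional[int]
    null: str = "fixed_margins"


@dataclass(frozen=True)
class PosthocCell:
    from_cat: str
    to_cat: str
    observed: int
    expected: float
    residual: float
    p_raw: float
    p_adj: float
    direction: str
    significant_over: bool


def possible_transition_count(categories: Sequence[str]) -> int:
    """Number of possible ordered category pairs, self-pairs included."""
    labels = list(dict.fromkeys(categories))
    return sum(1 for _ in labels for _ in labels)


def build_transitions(
    calls_by_tag: Mapping[str, Sequence[CallRecord]],
    bci_s: float,
    exclude_variable: bool = True,
) -> TransitionTable:
    """Gate consecutive same-tag call pairs at the bout criterion.

    One event per consecutive retained pair whose silent gap (clamped at
    0 for overlapping annotations) is <= ``bci_s``; transitions never
    span tags.  The category axis covers every label appearing in any
    retained event, identically on rows and columns.
    """
    if bci_s <= 0:
        raise ParameterError(f"bci_s must be positive, got {bci_s}")
    events: list[TransitionEvent] = []
    for tag_id, calls in calls_by_tag.items():
        calls = list(calls)
        check_sorted(calls)
        if exclude_variable:
            calls = [c for c in calls if not c.is_variable]
        for a, b in zip(calls, calls[1:]):
            gap = max(0.0, b.start_s - a.end_s)
            if gap <= bci_s:
                events.append(
                    TransitionEvent(
                        tag_id=tag_id,
                        from_call_id=a.call_id,
                        to_call_id=b.call_id,
                        from_cat=a.category,
                        to_cat=b.category,
                        gap_s=gap,
                        time_s=a.start_s,
                    )
                )
    categories = sorted({e.from_cat for e in events} | {e.to_cat for e in events})
    idx = {c: i for i, c in enumerate(categories)}
    counts = np.zeros((len(categories), len(categories)), dtype=int)
    for e in events:
        counts[idx[e.from_cat], idx[e.to_cat]] += 1
    return TransitionTable(categories=categories, counts=counts, events=events)


def expected_counts(table: TransitionTable) -> np.ndarray:
    """Independence-null expectations from the observed margins."""
    if table.n_total == 0:
        raise ParameterError("empty table: n_total = 0")
    counts = table.counts.astype(float)
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    return np.outer(rows, cols) / table.n_total


def _pearson_statistic(observed: np.ndarray, expected: np.ndarray) -> float:
    mask = expected > 0
    o = observed[mask].astype(float)
    e = expected[mask]
    return float(((o - e) ** 2 / e).sum())


def _check_testable(table: TransitionTable) -> np.ndarray:
    expected = expected_counts(table)
    rows = table.counts.sum(axis=1)
    cols = table.counts.sum(axis=0)
    if (rows > 0).sum() < 2 or (cols > 0).sum() < 2:
        raise DegenerateTableError(
            "test undefined: need at least two rows and two columns with "
            "positive margins"
        )
    return expected


def chi_square_mc(
    table: TransitionTable,
    n_sim: int = 2000,
    seed: Optional[int] = None,
    null: str = "fixed_margins",
) -> ChiSquareResult:
    """Pearson chi-squared with a Monte-Carlo p-value.

    The statistic sums over cells with positive expectation.  Null
    tables preserve both observed margins exactly (Patefield sampling);
    a multinomial null (total fixed, cells at independence proportions)
    is available behind ``null="multinomial"``.  The p-value uses the
    add-one convention ``(1 + #{sim >= obs}) / (n_sim + 1)``.
    """
    if n_sim < 1:
        raise ParameterError(f"n_sim must be >= 1, got {n_sim}")
    expected = _check_testable(table)
    observed_stat = _pearson_statistic(table.counts, expected)

    rows = table.counts.sum(axis=1)
    cols = table.counts.sum(axis=0)
    r_keep = np.flatnonzero(rows > 0)
    c_keep = np.flatnonzero(cols > 0)
    sub_e = expected[np.ix_(r_keep, c_keep)]

    rng = np.random.default_rng(seed)
    if null == "fixed_margins":
        sampler = stats.random_table(rows[r_keep], cols[c_keep])
        sims = sampler.rvs(n_sim, method="patefield", random_state=rng)
    elif null == "multinomial":
        probs = (sub_e / sub_e.sum()).ravel()
        draws = rng.multinomial(table.n_total, probs, size=n_sim)
        sims = draws.reshape(n_sim, *sub_e.shape)
    else:
        raise ParameterError(f"unknown null model {null!r}")

    sim_stats = (((sims - sub_e) ** 2) / sub_e).sum(axis=(1, 2))
    n_ge = int(np.count_nonzero(sim_stats >= observed_stat - 1e-12))
    p_mc = (1 + n_ge) / (n_sim + 1)
    return ChiSquareResult(statistic=observed_stat, p_mc=p_mc, n_sim=n_sim,
                           seed=seed, null=null)


def posthoc_residuals(
    table: TransitionTable,
    alpha: float = 0.05,
    family_size: Optional[int] = None,
) -> list[PosthocCell]:
    """Margin-adjusted standardized residual test for every cell.

    ``z = (O - E) / sqrt(E * (1 - row/n) * (1 - col/n))``, two-sided
    normal p-values, Bonferroni-corrected over ``family_size`` tests
    (default: all C^2 cells of the square table).  Cells with zero
    expectation are excluded and logged.  ``significant_over`` marks
    cells exceeding expectation after correction — the edges feeding
    combination-cluster extraction.
    """
    if not 0 < alpha < 1:
        raise ParameterError(f"alpha must lie in (0, 1), got {alpha}")
    expected = _check_testable(table)
    n = table.n_total
    counts = table.counts
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    c = len(table.categories)
    family = family_size if family_size is not None else c * c

    cells: list[PosthocCell] = []
    n_excluded = 0
    for i, from_cat in enumerate(table.categories):
        for j, to_cat in enumerate(table.categories):
            e = expected[i, j]
            if e <= 0:
                n_excluded += 1
                continue
            denom = e * (1 - rows[i] / n) * (1 - cols[j] / n)
            if denom <= 0:
                n_excluded += 1
                continue
            z = (counts[i, j] - e) / np.sqrt(denom)
            p_raw = float(2.0 * stats.norm.sf(abs(z)))
            p_adj = min(1.0, p_raw * family)
            cells.append(
                PosthocCell(
                    from_cat=from_cat,
                    to_cat=to_cat,
                    observed=int(counts[i, j]),
                    expected=float(e),
                    residual=float(z),
                    p_raw=p_raw,
                    p_adj=p_adj,
                    direction="over" if z > 0 else "under",
                    significant_over=bool(p_adj < alpha and z > 0),
                )
            )
    if n_excluded:
        log.info("posthoc_residuals: excluded %d cells with zero expectation "
                 "or degenerate margins", n_excluded)
    return cells


def filter_min_count(
    cells: Iterable[PosthocCell], min_count: int = 10
) -> list[PosthocCell]:
    """Cells observed strictly more than ``min_count`` times."""
    return [c for c in cells if c.observed > min_count]
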