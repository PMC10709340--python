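"""Inter-call gaps and the bout criterion interval (BCI).

Gaps are silent intervals: next call start minus previous call end,
computed only between consecutive retained calls within the same tag.
The gap distribution is modelled as a two-process exponential (Poisson)
mixture — a fast within-bout process and a slow between-bout process —
fitted by maximum likelihood on gaps below a 30 s cap.  The BCI is the
gap at which the two weighted component densities intersect:

    bci = ln( p*lf / ((1-p)*ls) ) / (lf - ls)

Gaps are pooled across tags for a single global criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.special import expit

from .records import (
    CallRecord,
    FitError,
    NoCriterionError,
    ParameterError,
    check_sorted,
)

log = logging.getLogger(__name__)

__all__ = [
    "GapEntry",
    "GapSeries",
    "BoutModel",
    "compute_gaps",
    "fit_bout_model",
    "bout_criterion",
    "mixture_loglik",
]

DEFAULT_MAX_GAP_S = 30.0


@dataclass(frozen=True)
class GapEntry:
    tag_id: str
    from_call_id: str
    to_call_id: str
    gap_s: float


@dataclass
class GapSeries:
    """Ordered within-tag gaps; never spans tags.

    ``clamped_ids`` lists the to-call ids of annotation overlaps whose
    negative raw gap was clamped to 0 (usable for sequence gating but
    excluded from likelihood fitting).
    """

    entries: list[GapEntry] = field(default_factory=list)
    clamped_ids: list[str] = field(default_factory=list)

    @property
    def gaps(self) -> np.ndarray:
        return np.array([e.gap_s for e in self.entries], dtype=float)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class BoutModel:
    """Fitted two-process mixture and its derived bout criterion."""

    p: float
    lambda_fast: float
    lambda_slow: float
    loglik: float
    n_gaps_used: int
    max_gap_s: float = DEFAULT_MAX_GAP_S
    bci_s: Optional[float] = None
    degenerate: bool = False
    start_logliks: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ParameterError(f"p must lie in (0, 1), got {self.p}")
        if not self.lambda_fast > self.lambda_slow > 0:
            raise ParameterError("need lambda_fast > lambda_slow > 0")


def compute_gaps(
    calls_by_tag: Mapping[str, Sequence[CallRecord]],
    exclude_variable: bool = True,
) -> GapSeries:
    """Silent gaps between consecutive retained calls within each tag.

    VARIABLE calls are removed first when ``exclude_variable``.  Negative
    gaps (overlapping annotations) are clamped to 0 and logged.
    """
    series = GapSeries()
    for tag_id, calls in calls_by_tag.items():
        calls = list(calls)
        check_sorted(calls)
        if exclude_variable:
            calls = [c for c in calls if not c.is_variable]
        for a, b in zip(calls, calls[1:]):
            gap = b.start_s - a.end_s
            if gap < 0:
                series.clamped_ids.append(b.call_id)
                gap = 0.0
            series.entries.append(
                GapEntry(tag_id=tag_id, from_call_id=a.call_id,
                         to_call_id=b.call_id, gap_s=gap)
            )
    if series.clamped_ids:
        log.info("compute_gaps: clamped %d negative gaps to 0",
                 len(series.clamped_ids))
    return series


def mixture_loglik(
    gaps: np.ndarray, p: float, lambda_fast: float, lambda_slow: float
) -> float:
    """Log-likelihood of gaps under the two-process exponential mixture."""
    t = np.asarray(gaps, dtype=float)
    lf = np.log(p) + np.log(lambda_fast) - lambda_fast * t
    ls = np.log1p(-p) + np.log(lambda_slow) - lambda_slow * t
    return float(np.logaddexp(lf, ls).sum())


def _nll(theta: np.ndarray, t: np.ndarray) -> float:
    p = expit(theta[0])
    lf, ls = np.exp(theta[1]), np.exp(theta[2])
    return -mixture_loglik(t, p, lf, ls)


def fit_bout_model(
    gaps: GapSeries | np.ndarray | Iterable[float],
    max_gap_s: float = DEFAULT_MAX_GAP_S,
    min_gaps: int = 50,
) -> BoutModel:
    """Maximum-likelihood fit of the two-process mixture.

    Only gaps with ``0 < t < max_gap_s`` enter the likelihood (the cap
    reduces bias from a few very long pauses; exact zeros come from
    clamped overlaps and are ill-suited to the density).  Deterministic
    multi-start optimisation over a fixed grid of moment- and
    quantile-based initial points; component order is enforced by
    relabelling so ``lambda_fast > lambda_slow`` always.
    """
    t = gaps.gaps if isinstance(gaps, GapSeries) else np.asarray(list(gaps), float)
    t = t[(t > 0) & (t < max_gap_s)]
    if len(t) < min_gaps:
        raise FitError(
            f"only {len(t)} usable gaps after the {max_gap_s} s cap "
            f"(need >= {min_gaps})"
        )

    med = float(np.median(t))
    fast0 = 1.0 / max(np.mean(t[t <= med]), 1e-6)
    slow0 = 1.0 / max(np.mean(t[t > med]), 1e-6)
    q25 = 1.0 / max(np.quantile(t, 0.25), 1e-6)
    q75 = 1.0 / max(np.quantile(t, 0.75), 1e-6)

    starts = []
    for p0 in (0.3, 0.5, 0.7, 0.9):
        for lf0, ls0 in ((fast0, slow0), (q25, q75), (2 * fast0, 0.5 * slow0)):
            if lf0 <= ls0:
                lf0, ls0 = 2.0 * ls0, 0.5 * lf0
            starts.append(np.array([np.log(p0 / (1 - p0)),
                                    np.log(lf0), np.log(ls0)]))

    best = None
    start_lls = []
    for x0 in starts:
        start_lls.append(-_nll(x0, t))
        res = optimize.minimize(_nll, x0, args=(t,), method="L-BFGS-B")
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FitError("mixture fit failed to converge from every start point")

    p = float(expit(best.x[0]))
    lf, ls = float(np.exp(best.x[1])), float(np.exp(best.x[2]))
    if lf < ls:  # relabel so the fast process has the larger rate
        lf, ls = ls, lf
        p = 1.0 - p
    if lf == ls:
        raise FitError("degenerate optimum: equal component rates")

    degenerate = p < 1e-3 or p > 1 - 1e-3 or lf / ls < 1.01
    p = min(max(p, 1e-12), 1 - 1e-12)
    try:
        bci = _bci(p, lf, ls)
    except NoCriterionError:
        bci = None
        degenerate = True
    if degenerate:
        log.warning("fit_bout_model: degenerate fit (p=%.4g, lf=%.4g, ls=%.4g)",
                    p, lf, ls)
    return BoutModel(
        p=p, lambda_fast=lf, lambda_slow=ls,
        loglik=-float(best.fun), n_gaps_used=len(t), max_gap_s=max_gap_s,
        bci_s=bci, degenerate=degenerate, start_logliks=tuple(start_lls),
    )


def _bci(p: float, lambda_fast: float, lambda_slow: float) -> float:
    num = p * lambda_fast
    den = (1.0 - p) * lambda_slow
    if num < den:
        raise NoCriterionError(
            f"fast process never dominates: p*lf = {num:.4g} < (1-p)*ls = {den:.4g}"
        )
    return float(np.log(num / den) / (lambda_fast - lambda_slow))


def bout_criterion(model: BoutModel) -> float:
    """Equal-density intersection of the two weighted components (seconds)."""
    return _bci(model.p, model.lambda_fast, model.lambda_slow)
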