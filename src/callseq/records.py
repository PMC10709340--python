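"""Core record types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: Reserved category label for calls that could not be classified.
VARIABLE_LABEL = "VARIABLE"

#: Quality rating admitted into the sequence analysis.
HIGH_QUALITY = "high"


class CallseqError(Exception):
    """Base class for all package errors."""


class ParameterError(CallseqError, ValueError):
    """An argument violates a documented precondition or invariant."""


class OrderingError(CallseqError, ValueError):
    """Input records are not sorted as required."""


class DegenerateInputError(CallseqError, ValueError):
    """Input is structurally valid but degenerate (e.g. all-zero signal)."""


class MeasurementUnavailableError(CallseqError, RuntimeError):
    """A measurement could not be taken; the item is flagged, not dropped."""


class FitError(CallseqError, RuntimeError):
    """Model fitting failed to converge on every start point."""


class NoCriterionError(CallseqError, ValueError):
    """The fitted mixture admits no bout criterion (fast process never dominates)."""


class DegenerateTableError(CallseqError, ValueError):
    """The contingency table is too degenerate for the requested test."""


class UndefinedShareError(CallseqError, ValueError):
    """A proportion was requested over an empty denominator."""


class LoadError(CallseqError, ValueError):
    """An input file failed schema validation; message lists offending rows."""


@dataclass(frozen=True)
class CallRecord:
    """One quality-rated, categorized call.

    Times are seconds from the start of the tag recording.  ``snr_db`` is
    optional because the level measurement is not always possible;
    ``snr_override`` marks calls retained despite a sub-threshold SNR
    (e.g. low-frequency noise contaminating the measurement band).
    """

    call_id: str
    tag_id: str
    start_s: float
    end_s: float
    category: str
    quality: str = HIGH_QUALITY
    snr_db: Optional[float] = None
    snr_override: bool = False

    def __post_init__(self) -> None:
        if self.end_s < self.start_s:
            raise ParameterError(
                f"call {self.call_id!r}: end_s ({self.end_s}) < start_s ({self.start_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def is_variable(self) -> bool:
        return self.category == VARIABLE_LABEL


@dataclass(frozen=True)
class TailSlapEvent:
    """A percussive tail-slap event on a tag's acoustic record."""

    tag_id: str
    time_s: float
    quality: str = HIGH_QUALITY


def sort_calls(calls: list[CallRecord]) -> list[CallRecord]:
    """Stable sort by start time."""
    return sorted(calls, key=lambda c: c.start_s)


def check_sorted(calls: list[CallRecord]) -> None:
    """Raise :class:`OrderingError` unless start times are non-decreasing."""
    for a, b in zip(calls, calls[1:]):
        if b.start_s < a.start_s:
            raise OrderingError(
                f"calls not sorted by start time: {a.call_id!r} ({a.start_s}) "
                f"precedes {b.call_id!r} ({b.start_s})"
            )
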