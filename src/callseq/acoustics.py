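"""Call-level SNR measurement and the quality gate.

SNR is the band-limited level of a call over its 90% energy duration
minus the level of a 200 ms call-free ambient segment shortly before the
call, after a 3rd-order Butterworth band-pass (450 Hz – 10 kHz).  The
filter is applied zero-phase (forward–backward) so annotation times are
not shifted.  Stored levels are relative (uncalibrated recordings): only
the difference, the SNR, is meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import signal

from .records import (
    HIGH_QUALITY,
    CallRecord,
    DegenerateInputError,
    MeasurementUnavailableError,
    ParameterError,
)

log = logging.getLogger(__name__)

__all__ = [
    "SNRMeasurement",
    "GateDecision",
    "bandpass",
    "energy_duration_90",
    "measure_snr",
    "quality_gate",
]

DEFAULT_LOW_HZ = 450.0
DEFAULT_HIGH_HZ = 10000.0
DEFAULT_ORDER = 3
NOISE_LEN_S = 0.200
DEFAULT_LOOKBACK_S = 5.0
DEFAULT_STEP_S = 0.050


@dataclass(frozen=True)
class SNRMeasurement:
    call_id: str
    spl_call_db: float
    spl_noise_db: float
    snr_db: float
    energy_window: tuple[float, float]
    noise_window: tuple[float, float]


@dataclass(frozen=True)
class GateDecision:
    call_id: str
    retained: bool
    reason: str


def bandpass(
    waveform: np.ndarray,
    sample_rate: float,
    low: float = DEFAULT_LOW_HZ,
    high: float = DEFAULT_HIGH_HZ,
    order: int = DEFAULT_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass of the stated order."""
    nyquist = sample_rate / 2.0
    if not 0 < low < high:
        raise ParameterError(f"need 0 < low < high, got {low}, {high}")
    if high >= nyquist:
        raise ParameterError(f"high cut-off {high} Hz >= Nyquist {nyquist} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=sample_rate,
                        output="sos")
    return signal.sosfiltfilt(sos, np.asarray(waveform, dtype=float))


def energy_duration_90(
    segment: np.ndarray, sample_rate: float
) -> tuple[float, float, float]:
    """Times (s, relative to segment start) at 5% and 95% cumulative energy.

    Returns ``(t5, t95, duration)`` where ``duration = t95 - t5``.
    """
    x = np.asarray(segment, dtype=float)
    if x.size == 0:
        raise DegenerateInputError("empty segment")
    energy = np.cumsum(x**2)
    total = energy[-1]
    if total <= 0:
        raise DegenerateInputError("segment has zero energy")
    i5 = int(np.searchsorted(energy, 0.05 * total))
    i95 = int(np.searchsorted(energy, 0.95 * total))
    t5 = i5 / sample_rate
    t95 = i95 / sample_rate
    return t5, t95, t95 - t5


def _spl_db(x: np.ndarray) -> float:
    ms = float(np.mean(np.asarray(x, dtype=float) ** 2))
    if ms <= 0:
        raise DegenerateInputError("zero-power segment")
    return 10.0 * np.log10(ms)


def _find_noise_window(
    call: CallRecord,
    all_calls: Sequence[CallRecord],
    lookback_s: float,
    step_s: float,
) -> tuple[float, float]:
    """Scan backwards in ``step_s`` steps for a 200 ms annotation-free stretch."""
    end = call.start_s
    earliest = max(0.0, call.start_s - lookback_s)
    while end - NOISE_LEN_S >= earliest - 1e-9:
        w0, w1 = end - NOISE_LEN_S, end
        overlaps = any(
            c.tag_id == call.tag_id
            and c.call_id != call.call_id
            and c.start_s < w1
            and c.end_s > w0
            for c in all_calls
        )
        if not overlaps:
            return w0, w1
        end -= step_s
    raise MeasurementUnavailableError(
        f"call {call.call_id!r}: no {NOISE_LEN_S * 1000:.0f} ms call-free "
        f"noise window within {lookback_s} s look-back"
    )


def measure_snr(
    waveform: np.ndarray,
    sample_rate: float,
    call: CallRecord,
    all_calls: Optional[Sequence[CallRecord]] = None,
    lookback_s: float = DEFAULT_LOOKBACK_S,
    step_s: float = DEFAULT_STEP_S,
    low: float = DEFAULT_LOW_HZ,
    high: float = DEFAULT_HIGH_HZ,
    order: int = DEFAULT_ORDER,
) -> SNRMeasurement:
    """SNR of one annotated call against a preceding ambient segment.

    Both segments are band-passed first; the call level is taken over the
    90% energy duration of the band-passed call segment.  Raises
    :class:`MeasurementUnavailableError` when no call-free 200 ms window
    exists in the look-back (the call should be flagged, not dropped).
    """
    fs = float(sample_rate)
    if all_calls is None:
        all_calls = [call]
    w0, w1 = _find_noise_window(call, all_calls, lookback_s, step_s)

    def cut(t0: float, t1: float) -> np.ndarray:
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        if i0 < 0 or i1 > len(waveform) or i1 <= i0:
            raise MeasurementUnavailableError(
                f"call {call.call_id!r}: segment [{t0}, {t1}] s outside waveform"
            )
        return np.asarray(waveform[i0:i1], dtype=float)

    call_seg = bandpass(cut(call.start_s, call.end_s), fs, low, high, order)
    noise_seg = bandpass(cut(w0, w1), fs, low, high, order)

    t5, t95, _ = energy_duration_90(call_seg, fs)
    j5, j95 = int(round(t5 * fs)), int(round(t95 * fs))
    j95 = max(j95, j5 + 1)
    spl_call = _spl_db(call_seg[j5:j95])
    spl_noise = _spl_db(noise_seg)
    return SNRMeasurement(
        call_id=call.call_id,
        spl_call_db=spl_call,
        spl_noise_db=spl_noise,
        snr_db=spl_call - spl_noise,
        energy_window=(call.start_s + t5, call.start_s + t95),
        noise_window=(w0, w1),
    )


def quality_gate(
    calls: Iterable[CallRecord],
    snr_threshold_db: float = 10.0,
    allow_low_snr_override: bool = True,
) -> tuple[list[CallRecord], list[GateDecision]]:
    """Select calls admitted to the sequence analysis.

    A call is retained iff it is rated high quality and either its SNR
    exceeds the threshold, its SNR was not measurable (no evidence to
    exclude), or it carries an explicit override flag.  VARIABLE calls
    pass this gate (they are removed later, in sequence construction).
    The audit log records a decision for every input call.
    """
    retained: list[CallRecord] = []
    audit: list[GateDecision] = []
    for call in calls:
        if call.quality != HIGH_QUALITY:
            audit.append(GateDecision(call.call_id, False, f"quality={call.quality}"))
            continue
        if call.snr_db is None:
            retained.append(call)
            audit.append(GateDecision(call.call_id, True, "snr_unmeasured"))
            continue
        if call.snr_db > snr_threshold_db:
            retained.append(call)
            audit.append(GateDecision(call.call_id, True, "snr_pass"))
        elif allow_low_snr_override and call.snr_override:
            retained.append(call)
            audit.append(GateDecision(call.call_id, True, "low_snr_override"))
        else:
            audit.append(
                GateDecision(call.call_id, False,
                             f"snr {call.snr_db:.1f} dB <= {snr_threshold_db:.1f} dB")
            )
    n_out = len(audit) - len(retained)
    if n_out:
        log.info("quality gate: %d retained, %d excluded", len(retained), n_out)
    return retained, audit
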