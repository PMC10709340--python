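"""Synthetic call-stream generator.

Produces annotation streams, tail-slap events and optional waveforms with
the statistical structure the downstream analysis assumes: bout-structured
silent gaps drawn from a two-process exponential mixture, planted
combination motifs with start/terminal ordering rules, frequent
same-emission repetition, unclassified (VARIABLE) calls, and tail slaps
temporally associated with a designated motif cluster.

Timing model
------------
Gaps *within* a motif instance (and between immediate repetitions) are
drawn from the fast process alone — motifs live inside bouts by
construction.  Gaps *between* emissions are drawn from the full
fast/slow mixture governed by ``TimingSpec.p_fast``.  Ground truth
(component labels, motif membership) is returned in a sidecar structure,
never in the annotation table itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import (
    VARIABLE_LABEL,
    CallRecord,
    ParameterError,
    TailSlapEvent,
)

__all__ = [
    "GrammarSpec",
    "TimingSpec",
    "GapSample",
    "MotifInstance",
    "TagTruth",
    "SyntheticTag",
    "generate_gaps",
    "generate_tag",
    "synthesize_waveform",
    "example_grammar",
    "annotation_frame",
    "tail_slap_frame",
    "truth_frame",
]


@dataclass(frozen=True)
class GrammarSpec:
    """Emission grammar: motifs with ordering rules plus background calls.

    Each emission event is either a motif instance (an ordered tuple of
    2–3 categories) or a single background call, chosen proportionally to
    ``motif_weights`` and ``background_weights``.  ``start_set`` /
    ``terminal_set``, when non-empty, constrain which categories may open
    or close a motif; every motif must satisfy them.
    """

    categories: tuple[str, ...]
    motifs: tuple[tuple[str, ...], ...] = ()
    motif_weights: tuple[float, ...] = ()
    start_set: frozenset[str] = frozenset()
    terminal_set: frozenset[str] = frozenset()
    repetition_prob: float = 0.0
    background_weights: dict[str, float] = field(default_factory=dict)
    variable_call_prob: float = 0.0

    def __post_init__(self) -> None:
        if not self.categories:
            raise ParameterError("grammar requires at least one category")
        cats = set(self.categories)
        if len(cats) != len(self.categories):
            raise ParameterError("duplicate category labels")
        if VARIABLE_LABEL in cats:
            raise ParameterError(f"{VARIABLE_LABEL!r} is reserved")
        if len(self.motifs) != len(self.motif_weights):
            raise ParameterError("motifs and motif_weights length mismatch")
        for motif in self.motifs:
            if not 2 <= len(motif) <= 3:
                raise ParameterError(f"motif {motif!r}: length must be 2 or 3")
            if not set(motif) <= cats:
                raise ParameterError(f"motif {motif!r} uses unknown categories")
            if self.start_set and motif[0] not in self.start_set:
                raise ParameterError(f"motif {motif!r} does not open with a start-set category")
            if self.terminal_set and motif[-1] not in self.terminal_set:
                raise ParameterError(f"motif {motif!r} does not close with a terminal-set category")
        if not set(self.start_set) <= cats or not set(self.terminal_set) <= cats:
            raise ParameterError("start/terminal sets must be subsets of categories")
        for p, name in ((self.repetition_prob, "repetition_prob"),
                        (self.variable_call_prob, "variable_call_prob")):
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {p}")
        weights = list(self.motif_weights) + list(self.background_weights.values())
        if any(w < 0 for w in weights):
            raise ParameterError("emission weights must be non-negative")
        if not any(w > 0 for w in weights):
            raise ParameterError("at least one emission weight must be positive")
        if not set(self.background_weights) <= cats:
            raise ParameterError("background_weights uses unknown categories")


@dataclass(frozen=True)
class TimingSpec:
    """Two-process gap mixture plus call-duration model.

    ``p_fast`` is the mixing proportion of the fast (within-bout)
    exponential component with rate ``lambda_fast`` (1/s); the slow
    (between-bout) component has rate ``lambda_slow``.
    """

    p_fast: float
    lambda_fast: float
    lambda_slow: float
    call_duration_mean: float = 0.5
    call_duration_sd: float = 0.1
    max_gap: float = 30.0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_fast < 1.0:
            raise ParameterError(f"p_fast must lie in (0, 1), got {self.p_fast}")
        if not self.lambda_fast > self.lambda_slow > 0.0:
            raise ParameterError(
                f"need lambda_fast > lambda_slow > 0, got "
                f"{self.lambda_fast}, {self.lambda_slow}"
            )
        if self.call_duration_mean <= 0 or self.call_duration_sd < 0:
            raise ParameterError("call durations must be positive")
        if self.max_gap <= 0:
            raise ParameterError("max_gap must be positive")


@dataclass(frozen=True)
class GapSample:
    """Gaps with their ground-truth component labels (True = fast)."""

    gaps: np.ndarray
    fast: np.ndarray

    def __len__(self) -> int:
        return len(self.gaps)


@dataclass(frozen=True)
class MotifInstance:
    motif_index: int
    categories: tuple[str, ...]
    call_ids: tuple[str, ...]
    start_s: float


@dataclass
class TagTruth:
    """Sidecar ground truth; never written into the annotation table."""

    motif_instances: list[MotifInstance] = field(default_factory=list)
    #: per call: index into motif_instances, or -1
    motif_membership: list[int] = field(default_factory=list)
    #: per call: component of the gap preceding it ("fast"/"slow"/"none")
    gap_component: list[str] = field(default_factory=list)


@dataclass
class SyntheticTag:
    tag_id: str
    calls: list[CallRecord]
    tail_slaps: list[TailSlapEvent]
    truth: TagTruth

    def __post_init__(self) -> None:
        starts = [c.start_s for c in self.calls]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ParameterError("call start times must be strictly increasing")


def generate_gaps(timing: TimingSpec, n: int, seed: int) -> GapSample:
    """Draw ``n`` silent gaps from the two-process exponential mixture.

    Each gap has density ``p*lf*exp(-lf*t) + (1-p)*ls*exp(-ls*t)``.
    Reproducible under a fixed seed; component labels are retained.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    fast = rng.random(n) < timing.p_fast
    rates = np.where(fast, timing.lambda_fast, timing.lambda_slow)
    gaps = rng.exponential(1.0 / rates)
    return GapSample(gaps=gaps, fast=fast)


def _positive_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    # rejection-free truncation: resample is overkill for a fixture
    return max(0.05, float(rng.normal(mean, sd)))


def generate_tag(
    grammar: GrammarSpec,
    timing: TimingSpec,
    n_calls: int,
    slap_cluster: Optional[frozenset[str] | set[str]] = None,
    seed: int = 0,
    tag_id: str = "synth",
    slap_assoc_prob: float = 1.0,
    slap_window_s: float = 300.0,
) -> SyntheticTag:
    """Emit a bout-structured call stream of at least ``n_calls`` calls.

    Motif instances are never truncated, so the stream may exceed
    ``n_calls`` by up to two calls.

    Interleaves motif instances, repetitions, background and VARIABLE
    calls.  When ``slap_cluster`` is given, each planted motif instance
    whose categories all belong to that cluster receives (with
    probability ``slap_assoc_prob``) a tail slap placed uniformly within
    ``slap_window_s`` of its start.
    """
    if n_calls < 1:
        raise ParameterError(f"n_calls must be >= 1, got {n_calls}")
    rng = np.random.default_rng(seed)

    emissions: list[tuple[str, ...] | None] = [None] * len(grammar.motifs)
    weights = list(grammar.motif_weights)
    bg_cats = [c for c, w in grammar.background_weights.items() if w > 0]
    for c in bg_cats:
        emissions.append((c,))
        weights.append(grammar.background_weights[c])
    for i, motif in enumerate(grammar.motifs):
        emissions[i] = motif
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ParameterError("no emission has positive weight")
    w = w / w.sum()

    calls: list[CallRecord] = []
    truth = TagTruth()
    t = 0.0
    counter = 0

    def emit_call(category: str, gap_component: str, motif_idx: int) -> str:
        nonlocal t, counter
        dur = _positive_normal(rng, timing.call_duration_mean, timing.call_duration_sd)
        cid = f"{tag_id}_c{counter:05d}"
        calls.append(
            CallRecord(call_id=cid, tag_id=tag_id, start_s=round(t, 6),
                       end_s=round(t + dur, 6), category=category)
        )
        truth.motif_membership.append(motif_idx)
        truth.gap_component.append(gap_component)
        t += dur
        counter += 1
        return cid

    def fast_gap() -> float:
        return float(rng.exponential(1.0 / timing.lambda_fast))

    def between_gap() -> tuple[float, str]:
        if rng.random() < timing.p_fast:
            return fast_gap(), "fast"
        return float(rng.exponential(1.0 / timing.lambda_slow)), "slow"

    first = True
    while counter < n_calls:
        if first:
            gap, component = 0.0, "none"
            first = False
        else:
            gap, component = between_gap()
        t += gap

        if rng.random() < grammar.variable_call_prob:
            emit_call(VARIABLE_LABEL, component, -1)
            continue

        choice = int(rng.choice(len(emissions), p=w))
        motif = emissions[choice]
        is_motif = choice < len(grammar.motifs)
        while True:  # emission plus geometric repetitions; motifs never truncated
            instance_start = t
            midx = len(truth.motif_instances) if is_motif else -1
            ids = []
            for j, cat in enumerate(motif):
                if j > 0:
                    t += fast_gap()
                ids.append(emit_call(cat, component if j == 0 else "fast", midx))
            if is_motif:
                truth.motif_instances.append(
                    MotifInstance(motif_index=choice, categories=tuple(motif),
                                  call_ids=tuple(ids), start_s=instance_start)
                )
            if counter >= n_calls or rng.random() >= grammar.repetition_prob:
                break
            t += fast_gap()
            component = "fast"

    tail_slaps: list[TailSlapEvent] = []
    if slap_cluster is not None:
        cluster = frozenset(slap_cluster)
        for inst in truth.motif_instances:
            if set(inst.categories) <= cluster and rng.random() < slap_assoc_prob:
                offset = float(rng.uniform(-slap_window_s, slap_window_s))
                tail_slaps.append(
                    TailSlapEvent(tag_id=tag_id,
                                  time_s=max(0.0, inst.start_s + offset))
                )
        tail_slaps.sort(key=lambda s: s.time_s)

    return SyntheticTag(tag_id=tag_id, calls=calls, tail_slaps=tail_slaps, truth=truth)


def synthesize_waveform(
    tag: SyntheticTag,
    sample_rate: float = 48000.0,
    call_band: tuple[float, float] = (1000.0, 8000.0),
    call_snr_db: float = 15.0,
    seed: int = 0,
    noise_sigma: float = 0.05,
    duration_s: Optional[float] = None,
    measurement_band: tuple[float, float] = (450.0, 10000.0),
) -> tuple[np.ndarray, float]:
    """Render the tag as tonal sweeps embedded in Gaussian noise.

    Each annotated call is a linear chirp spanning ``call_band`` whose
    band-limited power is ``call_snr_db`` dB above the ambient noise
    power in ``measurement_band`` (the analysis band), so the nominal
    per-call SNR equals ``call_snr_db`` by construction.  Background
    noise is gated out within call windows so the nominal value is exact.
    Returns ``(waveform, sample_rate)``.
    """
    from scipy import signal

    fs = float(sample_rate)
    lo, hi = call_band
    if not 0 < lo < hi:
        raise ParameterError("call_band must satisfy 0 < low < high")
    if fs < 2.0 * max(hi, measurement_band[1]):
        raise ParameterError(
            f"sample_rate {fs} below twice the upper band edge"
        )
    rng = np.random.default_rng(seed)

    if duration_s is None:
        duration_s = (tag.calls[-1].end_s + 1.0) if tag.calls else 1.0
    n = int(round(duration_s * fs))
    wave = rng.standard_normal(n) * noise_sigma

    # Noise power surviving the zero-phase measurement band-pass:
    # filtfilt applies |H|^2, so power gain is mean |H|^4 over frequency.
    sos = signal.butter(3, measurement_band, btype="bandpass", fs=fs, output="sos")
    freqs, h = signal.sosfreqz(sos, worN=8192, fs=fs)
    gain = float(np.mean(np.abs(h) ** 4))
    p_noise_band = noise_sigma**2 * gain

    amp = np.sqrt(2.0 * p_noise_band * 10.0 ** (call_snr_db / 10.0))
    for call in tag.calls:
        i0 = int(round(call.start_s * fs))
        i1 = min(int(round(call.end_s * fs)), n)
        if i1 <= i0:
            continue
        tt = np.arange(i1 - i0) / fs
        tone = amp * signal.chirp(tt, f0=lo, t1=tt[-1] if len(tt) > 1 else 1.0 / fs,
                                  f1=hi, method="linear")
        wave[i0:i1] = tone
    return wave, fs


def example_grammar() -> GrammarSpec:
    """A demonstration grammar with three motif families.

    The largest family uses six categories with designated opening calls
    (I38.1, I38.2) and a single terminal call (I69) on three-call motifs.
    """
    motifs = (
        ("I38.1", "I11.4"),
        ("I38.1", "I39"),
        ("I38.2", "I77"),
        ("I38.1", "I11.4", "I69"),
        ("I38.1", "I39", "I69"),
        ("I38.2", "I77", "I69"),
        ("I63", "I72.3"),
        ("I43.2", "I45"),
        ("I44", "I45"),
        ("I46", "I45"),
    )
    weights = (4.0, 1.0, 1.5, 2.0, 0.5, 0.8, 3.0, 1.0, 1.0, 1.0)
    background = {c: 0.4 for c in ("I5", "I16", "I22", "I30", "I55", "I60")}
    categories = tuple(sorted({c for m in motifs for c in m} | set(background)))
    return GrammarSpec(
        categories=categories,
        motifs=motifs,
        motif_weights=weights,
        start_set=frozenset({"I38.1", "I38.2", "I63", "I43.2", "I44", "I46"}),
        terminal_set=frozenset(
            {"I11.4", "I39", "I77", "I69", "I72.3", "I45"}
        ),
        repetition_prob=0.3,
        background_weights=background,
        variable_call_prob=0.05,
    )


def annotation_frame(tags: Sequence[SyntheticTag]) -> pd.DataFrame:
    """Annotation table (one row per call) across tags."""
    rows = [
        {
            "call_id": c.call_id,
            "tag_id": c.tag_id,
            "start_s": c.start_s,
            "end_s": c.end_s,
            "category": c.category,
            "quality": c.quality,
            "snr_db": c.snr_db if c.snr_db is not None else "",
        }
        for tag in tags
        for c in tag.calls
    ]
    return pd.DataFrame(rows, columns=["call_id", "tag_id", "start_s", "end_s",
                                       "category", "quality", "snr_db"])


def tail_slap_frame(tags: Sequence[SyntheticTag]) -> pd.DataFrame:
    rows = [
        {"tag_id": s.tag_id, "time_s": s.time_s, "quality": s.quality}
        for tag in tags
        for s in tag.tail_slaps
    ]
    return pd.DataFrame(rows, columns=["tag_id", "time_s", "quality"])


def truth_frame(tags: Sequence[SyntheticTag]) -> pd.DataFrame:
    """Sidecar truth: per-call motif membership and gap component."""
    rows = []
    for tag in tags:
        for call, midx, comp in zip(
            tag.calls, tag.truth.motif_membership, tag.truth.gap_component
        ):
            rows.append(
                {
                    "call_id": call.call_id,
                    "tag_id": tag.tag_id,
                    "motif_instance": midx,
                    "gap_component": comp,
                }
            )
    return pd.DataFrame(rows, columns=["call_id", "tag_id", "motif_instance",
                                       "gap_component"])
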