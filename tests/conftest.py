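from __future__ import annotations

import pytest

from callseq.records import CallRecord
from callseq.synthetic import GrammarSpec, TimingSpec


def make_call(call_id, start, end, category, tag_id="t1", quality="high",
              snr_db=None, override=False):
    return CallRecord(
        call_id=str(call_id), tag_id=tag_id, start_s=float(start),
        end_s=float(end), category=category, quality=quality,
        snr_db=snr_db, snr_override=override,
    )


@pytest.fixture
def default_timing() -> TimingSpec:
    return TimingSpec(p_fast=0.7, lambda_fast=2.0, lambda_slow=0.05)


@pytest.fixture
def two_motif_grammar() -> GrammarSpec:
    """Two motifs with disjoint category sets plus weak background."""
    return GrammarSpec(
        categories=("A", "B", "C", "D", "E", "F", "G", "H"),
        motifs=(("A", "B"), ("C", "D")),
        motif_weights=(4.0, 4.0),
        background_weights={c: 0.3 for c in ("E", "F", "G", "H")},
        repetition_prob=0.2,
        variable_call_prob=0.05,
    )


@pytest.fixture
def recovery_timing() -> TimingSpec:
    """Slow between-emission mixing so motifs dominate gated transitions."""
    return TimingSpec(p_fast=0.02, lambda_fast=2.0, lambda_slow=0.01,
                      call_duration_mean=0.4, call_duration_sd=0.05)
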