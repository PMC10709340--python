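"""Readers, writers, configuration and the end-to-end pipeline.

Times are seconds from tag start.  Category labels are opaque strings;
the reserved label ``VARIABLE`` marks unclassified calls.  All artifacts
are plain text (CSV/JSON) and round-trip exactly; two runs with the same
configuration and seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .acoustics import GateDecision, quality_gate
from .bouts import (
    DEFAULT_MAX_GAP_S,
    BoutModel,
    GapSeries,
    bout_criterion,
    compute_gaps,
    fit_bout_model,
)
from .clusters import (
    CombinationCluster,
    ShareSummary,
    ValidatedSequence,
    extract_clusters,
    summarize_shares,
    validate_sequences,
)
from .context import ContextSummary, context_summary, label_feeding
from .markov import (
    ChiSquareResult,
    PosthocCell,
    TransitionTable,
    build_transitions,
    chi_square_mc,
    posthoc_residuals,
)
from .records import CallRecord, LoadError, ParameterError, TailSlapEvent

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "read_annotations",
    "read_tail_slaps",
    "read_audacity_labels",
    "run_pipeline",
]

REQUIRED_COLUMNS = ("tag_id", "start_s", "end_s", "category", "quality")


def read_annotations(path: str | Path) -> dict[str, list[CallRecord]]:
    """Load a call annotation CSV into per-tag sorted call lists.

    Required columns: tag_id, start_s, end_s, category, quality.
    Optional: call_id (auto-assigned from row number when absent),
    snr_db, snr_override.  Schema violations are reported with 1-based
    data row numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"tag_id": str, "category": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing required columns {missing}")

    problems: list[str] = []
    for col in ("start_s", "end_s"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        problems.extend(f"row {i + 1}: non-numeric {col}" for i in bad)
    if problems:
        raise LoadError(f"{path}: " + "; ".join(problems))
    df["start_s"] = df["start_s"].astype(float)
    df["end_s"] = df["end_s"].astype(float)

    bad = df.index[df["end_s"] < df["start_s"]]
    problems.extend(f"row {i + 1}: end_s < start_s" for i in bad)

    if "call_id" in df.columns:
        ids = df["call_id"].astype(str)
        dup = ids[ids.duplicated()]
        problems.extend(f"row {i + 1}: duplicated call_id {v!r}"
                        for i, v in dup.items())
    else:
        ids = pd.Series([f"row{i + 1}" for i in df.index], index=df.index)

    if problems:
        raise LoadError(f"{path}: " + "; ".join(problems))

    has_snr = "snr_db" in df.columns
    has_override = "snr_override" in df.columns
    by_tag: dict[str, list[CallRecord]] = {}
    for i, row in df.iterrows():
        snr = None
        if has_snr and pd.notna(row["snr_db"]) and str(row["snr_db"]).strip() != "":
            snr = float(row["snr_db"])
        override = bool(row["snr_override"]) if has_override and pd.notna(
            row.get("snr_override")) else False
        call = CallRecord(
            call_id=str(ids.loc[i]),
            tag_id=str(row["tag_id"]),
            start_s=float(row["start_s"]),
            end_s=float(row["end_s"]),
            category=str(row["category"]),
            quality=str(row["quality"]),
            snr_db=snr,
            snr_override=override,
        )
        by_tag.setdefault(call.tag_id, []).append(call)
    for calls in by_tag.values():
        calls.sort(key=lambda c: c.start_s)
    return by_tag


def read_tail_slaps(path: str | Path) -> list[TailSlapEvent]:
    """Load a tail-slap CSV (tag_id, time_s, quality)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"tag_id": str})
    for col in ("tag_id", "time_s", "quality"):
        if col not in df.columns:
            raise LoadError(f"{path}: missing column {col!r}")
    return [
        TailSlapEvent(tag_id=str(r["tag_id"]), time_s=float(r["time_s"]),
                      quality=str(r["quality"]))
        for _, r in df.iterrows()
    ]


def read_audacity_labels(path: str | Path) -> list[tuple[float, float, str]]:
    """Read an Audacity label track (tab-separated start, end, label)."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("\\"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise LoadError(f"{path}: line {lineno}: expected 3 tab-separated fields")
        out.append((float(parts[0]), float(parts[1]), parts[2]))
    return out


# --------------------------------------------------------------------------
# configuration & pipeline


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end run, mirroring the method's constants."""

    annotations: str
    out_dir: str
    tail_slaps: Optional[str] = None
    snr_threshold_db: float = 10.0
    allow_low_snr_override: bool = True
    max_gap_s: float = DEFAULT_MAX_GAP_S
    n_sim: int = 2000
    alpha: float = 0.05
    min_count: int = 10
    window_s: float = 300.0
    bci_override: Optional[float] = None
    exclude_variable: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("snr_threshold_db", "max_gap_s", "window_s"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must lie in (0, 1)")
        if self.n_sim < 1 or self.min_count < 0:
            raise ParameterError("n_sim >= 1 and min_count >= 0 required")
        if self.bci_override is not None and self.bci_override <= 0:
            raise ParameterError("bci_override must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


@dataclass
class PipelineResult:
    config: PipelineConfig
    retained: dict[str, list[CallRecord]]
    audit: list[GateDecision]
    gaps: GapSeries
    bout_model: Optional[BoutModel]
    bci_s: float
    table: TransitionTable
    chi_square: ChiSquareResult
    posthoc: list[PosthocCell]
    clusters: list[CombinationCluster]
    sequences: list[ValidatedSequence]
    shares: ShareSummary
    context: Optional[ContextSummary]
    out_dir: Path


def _json_dump(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _events_frame(table: TransitionTable) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(e) for e in table.events],
        columns=["tag_id", "from_call_id", "to_call_id", "from_cat", "to_cat",
                 "gap_s", "time_s"],
    )


def _table_long_frame(table: TransitionTable) -> pd.DataFrame:
    rows = []
    for i, a in enumerate(table.categories):
        for j, b in enumerate(table.categories):
            count = int(table.counts[i, j])
            if count:
                rows.append({"from_cat": a, "to_cat": b, "count": count})
    return pd.DataFrame(rows, columns=["from_cat", "to_cat", "count"])


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage in order and write all artifacts.

    quality gate -> gaps -> bout model (unless ``bci_override``) ->
    transitions -> chi-squared -> post-hoc -> clusters -> sequences ->
    shares -> feeding context (when tail slaps are provided).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    calls_by_tag = read_annotations(config.annotations)
    n_in = sum(len(v) for v in calls_by_tag.values())

    retained: dict[str, list[CallRecord]] = {}
    audit: list[GateDecision] = []
    for tag_id, calls in calls_by_tag.items():
        kept, decisions = quality_gate(
            calls, config.snr_threshold_db, config.allow_low_snr_override
        )
        if kept:
            retained[tag_id] = kept
        audit.extend(decisions)
    n_kept = sum(len(v) for v in retained.values())
    log.info("gate: %d calls in, %d retained", n_in, n_kept)
    pd.DataFrame([dataclasses.asdict(d) for d in audit],
                 columns=["call_id", "retained", "reason"]).to_csv(
        out_dir / "gate_audit.csv", index=False)

    gaps = compute_gaps(retained, exclude_variable=config.exclude_variable)
    pd.DataFrame(
        [dataclasses.asdict(e) for e in gaps.entries],
        columns=["tag_id", "from_call_id", "to_call_id", "gap_s"],
    ).to_csv(out_dir / "gaps.csv", index=False)
    log.info("gaps: %d within-tag gaps", len(gaps))

    bout_model: Optional[BoutModel] = None
    if config.bci_override is not None:
        bci_s = config.bci_override
        log.info("bout model skipped: BCI override %.3f s", bci_s)
    else:
        bout_model = fit_bout_model(gaps, max_gap_s=config.max_gap_s)
        bci_s = bout_criterion(bout_model)
        _json_dump(
            {
                "p": bout_model.p,
                "lambda_fast": bout_model.lambda_fast,
                "lambda_slow": bout_model.lambda_slow,
                "loglik": bout_model.loglik,
                "n_gaps_used": bout_model.n_gaps_used,
                "max_gap_s": bout_model.max_gap_s,
                "bci_s": bci_s,
                "degenerate": bout_model.degenerate,
            },
            out_dir / "bout_model.json",
        )
        log.info("bout model: BCI %.3f s from %d gaps", bci_s,
                 bout_model.n_gaps_used)

    table = build_transitions(retained, bci_s,
                              exclude_variable=config.exclude_variable)
    _events_frame(table).to_csv(out_dir / "events.csv", index=False)
    _table_long_frame(table).to_csv(out_dir / "transitions.csv", index=False)
    log.info("transitions: %d gated events, %d categories",
             table.n_total, len(table.categories))

    chi = chi_square_mc(table, n_sim=config.n_sim, seed=config.seed)
    _json_dump(
        {"statistic": chi.statistic, "p_mc": chi.p_mc, "n_sim": chi.n_sim,
         "seed": chi.seed, "null": chi.null},
        out_dir / "chi_square.json",
    )

    cells = posthoc_residuals(table, alpha=config.alpha)
    pd.DataFrame([dataclasses.asdict(c) for c in cells]).to_csv(
        out_dir / "posthoc.csv", index=False)

    clusters = extract_clusters(cells, min_count=config.min_count)
    _json_dump(
        [
            {
                "cluster_id": c.cluster_id,
                "categories": sorted(c.categories),
                "edges": [list(e) for e in c.edges],
                "n_transitions": c.n_transitions,
            }
            for c in clusters
        ],
        out_dir / "clusters.json",
    )
    log.info("clusters: %d extracted", len(clusters))

    sequences = validate_sequences(
        retained, bci_s, cells, clusters,
        exclude_variable=config.exclude_variable,
    )
    pd.DataFrame(
        [
            {
                "tag_id": s.tag_id,
                "call_ids": "|".join(s.call_ids),
                "categories": "|".join(s.categories),
                "length": s.length,
                "cluster_id": s.cluster_id if s.cluster_id else "",
                "start_s": s.start_s,
            }
            for s in sequences
        ],
        columns=["tag_id", "call_ids", "categories", "length", "cluster_id",
                 "start_s"],
    ).to_csv(out_dir / "sequences.csv", index=False)

    shares = summarize_shares(table, clusters)
    _json_dump(
        {
            "n_total": shares.n_total,
            "n_repetition": shares.n_repetition,
            "repetition_share": shares.repetition_share,
            "n_cluster": shares.n_cluster,
            "cluster_share": shares.cluster_share,
            "per_cluster": shares.per_cluster,
        },
        out_dir / "shares.json",
    )

    context: Optional[ContextSummary] = None
    if config.tail_slaps:
        slaps = read_tail_slaps(config.tail_slaps)
        labeled = label_feeding(table.events, slaps, window_s=config.window_s)
        context = context_summary(labeled, clusters)
        _json_dump(
            {
                "n_total": context.n_total,
                "n_feeding": context.n_feeding,
                "proportion_feeding": context.proportion_feeding,
                "proportion_non_feeding": context.proportion_non_feeding,
                "per_cluster": {
                    cid: dataclasses.asdict(cc)
                    for cid, cc in context.per_cluster.items()
                },
            },
            out_dir / "context.json",
        )
        pd.DataFrame(
            [
                {**dataclasses.asdict(item.event), "feeding": item.feeding}
                for item in labeled
            ]
        ).to_csv(out_dir / "labeled_events.csv", index=False)

    _json_dump(
        {
            "callseq_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "funnel": {
                "calls_in": n_in,
                "calls_retained": n_kept,
                "gaps": len(gaps),
                "gated_transitions": table.n_total,
                "observed_pairs": int((table.counts > 0).sum()),
            },
        },
        out_dir / "manifest.json",
    )

    return PipelineResult(
        config=config, retained=retained, audit=audit, gaps=gaps,
        bout_model=bout_model, bci_s=bci_s, table=table, chi_square=chi,
        posthoc=cells, clusters=clusters, sequences=sequences, shares=shares,
        context=context, out_dir=out_dir,
    )
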