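# callseq

Analysis pipeline for bout-structured animal call sequences:

1. **Acoustic quality** — band-limited SNR measurement (3rd-order Butterworth
   450 Hz–10 kHz, zero-phase; call level over the 90% energy duration vs. a
   200 ms preceding ambient segment) and a 10 dB quality gate with an audit
   log.
2. **Bout analysis** — silent inter-call gaps (next start − previous end,
   within tag), maximum-likelihood fit of a two-process exponential (Poisson)
   mixture on gaps below a 30 s cap, and the bout criterion interval (BCI)
   at the equal-density intersection of the weighted components.
3. **Markov transitions** — BCI-gated first-order transition table, Pearson
   chi-squared with Monte-Carlo p-values from fixed-margins (Patefield) null
   tables, and post-hoc margin-adjusted standardized residuals with a
   Bonferroni correction.
4. **Combination clusters** — weakly connected components of significant
   over-expected mixed-category transitions (count > 10), validated
   multi-call sequences, and repetition/combination share summaries.
5. **Context association** — feeding labels from tail-slap proximity
   (symmetric 5-minute window) with per-cluster proportions.
6. **Synthetic data** — a seeded generator for bout-structured call streams
   with planted combination grammars (start/terminal ordering rules,
   repetitions, VARIABLE calls), tail slaps, and waveform rendering with
   controlled SNR, so the whole pipeline is testable without recordings.

## CLI

```sh
callseq simulate --n-calls 500 --n-tags 3 --seed 0 --out demo/        # synthetic dataset
callseq bci --annotations demo/annotations.csv --out bci.json          # bout model + BCI
callseq transitions --annotations demo/annotations.csv --bci 1.72 \
    --out trans/                                                       # chi-squared + post-hoc
callseq clusters --annotations demo/annotations.csv --bci 1.72 \
    --out clusters.json                                                # clusters + shares
callseq context --annotations demo/annotations.csv \
    --tail-slaps demo/tail_slaps.csv --bci 1.72 --out context.json     # feeding association
callseq snr --wav demo/tag00.wav --annotations demo/annotations.csv \
    --tag tag00 --out snr.csv                                          # per-call SNR
```

Or run everything from a config file:

```sh
cat > config.yaml <<EOF
annotations: demo/annotations.csv
tail_slaps: demo/tail_slaps.csv
out_dir: out
n_sim: 2000
seed: 0
# bci_override: 1.72   # optional: skip the bout-model fit
EOF
callseq run-all --config config.yaml
```

Artifacts (all plain CSV/JSON, byte-identical across reruns with the same
seed): `gate_audit.csv`, `gaps.csv`, `bout_model.json`, `events.csv`,
`transitions.csv`, `chi_square.json`, `posthoc.csv`, `clusters.json`,
`sequences.csv`, `shares.json`, `context.json`, `manifest.json`.

## Input formats

- Annotation CSV: `tag_id, start_s, end_s, category, quality` (+ optional
  `call_id`, `snr_db`, `snr_override`). Times are seconds from tag start.
  The reserved category `VARIABLE` marks unclassified calls.
- Tail-slap CSV: `tag_id, time_s, quality`.
- WAV (via scipy) and Audacity label tracks for the acoustic stage.

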