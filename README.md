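# edgame

A headless, seedable re-implementation of a scoring-based serious game for
pediatric emergency-department (ED) logistics, together with the full
telemetry-analytics chain used to study it: behavior coding, lag sequential
analysis (LSA), engagement-to-performance regression, and Likert
questionnaire dimension scoring. Everything runs on synthetic data; there
are no external inputs.

## What it does

* **`edgame.profile_deck`** — generates the synthetic patient-profile deck
  (default 90 unique cards, each with an urgency flag and a planned list of
  care activities with staff requirements) and per-round arrival schedules
  (truncated Poisson, drawn without replacement). JSON and flat-CSV
  round-trip I/O.
* **`edgame.game_engine`** — executes a full session over discrete rounds
  (default 12 rounds × 30 min = 6 h; 5 modules, one red) with bot players:
  arrivals → triage → staff allocation → activity ticks → discharges →
  scoring. Urgent patients are hard-routed to the red module. Emits a JSON
  Lines telemetry log; identical seeds give byte-identical logs.
* **`edgame.scoring`** — the token mechanic over four logistical indicators
  (production throughput, activity execution, resource management,
  production resilience) with role-specific rewards/penalties (red module
  magnitudes 4× normal; triage earns a quarter share of throughput and
  loses 1 token per 2 rejections). Pure, idempotent function of the event
  log, plus a positive:negative feedback-ratio calibration check targeting
  roughly 6:1.
* **`edgame.behavior_coding`** — transcribes events into behavior codes
  (MR, EP, IC, FT) and stimulus codes (RA + indicator), and derives
  per-player engagement attributes (counts, time on task, token
  performance).
* **`edgame.lag_sequential`** — lag-1 transition counts pooled per player,
  adjusted-residual z-scores, significance-thresholded transition graphs,
  CSV/DOT export.
* **`edgame.engagement_stats`** — OLS of performance on the four
  engagement counts (R², ΔR², B, SE, standardized β, p, F) and a
  parameter-recovery harness on a declared generative model.
* **`edgame.geq_scoring`** — Likert item → dimension mean scoring with a
  bundled non-normative dimension-map template, and paired dimension
  comparison (Wilcoxon signed-rank by default).
* **`edgame.cli_io`** — config schema, run manifest with content hashes,
  and the end-to-end pipeline.

## CLI

```bash
edgame deck --size 90 --urgent-fraction 0.15 --seed 1 --out deck.json
edgame arrivals --deck deck.json --rounds 12 --mean-per-round 3 --seed 1 --out sched.csv
edgame simulate --deck deck.json --schedule sched.csv --seed 1 --out log.jsonl
edgame score --log log.jsonl --out ledger.csv
edgame code --log log.jsonl --out seqs.csv
edgame lsa --sequences seqs.csv --threshold 1.96 --out-prefix lsa_
edgame regress --data engagement.csv --out regression.csv
edgame geq --responses responses.csv --map geq_map.json --out scores.csv
edgame pipeline --seed 1 --out run/        # full chain + manifest.json
```

All commands accept `--verbose` on the group for stage logging. The
pipeline config is a JSON file with only known keys (unknown keys are
rejected); see `edgame.cli_io.PipelineConfig` for the schema and defaults.

## Notes on defaults

The source study does not publish its patient-flow statistics, staff pools,
or module capacities. Defaults here (case mix, urgent fraction 0.15, mean
3 arrivals/round, 3 doctors + 6 nurses per module, capacity 4) are declared
assumptions chosen so the default scenario lands near the 6:1
positive-to-negative feedback design ratio; every one is configurable.
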