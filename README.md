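# lyricbias

Inference of cultural transmission biases — success, prestige, content and
unbiased (drift) transmission — on the emotional valence of song lyrics.

The package turns a lyrics corpus into per-song sentiment counts, builds
lagged transmission-bias covariates, fits Bayesian aggregated-binomial
multilevel models (varying intercepts for artist, genre and year) with a
built-in Hamiltonian Monte Carlo sampler, and compares models by WAIC.
A generative corpus simulator with known coefficients makes the entire
pipeline testable offline, including parameter-recovery and neutral-drift
calibration experiments.

## Modules

| module | purpose |
| --- | --- |
| `lyricbias.corpus` | read/clean chart CSV and sparse bag-of-words corpora; stemming, English heuristic, year filter, artist-name clustering, collaboration splitting |
| `lyricbias.sentiment` | stem-lexicon valence coding (positive / negative / neither), per-song counts, yearly trend series |
| `lyricbias.covariates` | lagged success / prestige / unbiased covariates and model-ready design assembly |
| `lyricbias.model` | aggregated-binomial multilevel model: likelihood, priors, HMC fit, posterior summaries, odds interpretation |
| `lyricbias.compare` | WAIC and model-comparison tables (deltas, SEs, weights) |
| `lyricbias.simulate` | generative corpus simulator (biased and pure-drift regimes) and recovery experiments |
| `lyricbias.pipeline` / `lyricbias.cli` | end-to-end orchestration and `lyricbias` command-line interface |

Notes:

* Stemming uses a vendored Porter stemmer with a small documented dialect
  extension (`adverbial_li`) so morphological families such as
  *happy / happily / happiness* share one stem.
* The repository ships only a tiny **open placeholder lexicon**
  (20 positive + 20 negative patterns) for tests and demos. Real analyses
  require user-supplied sentiment dictionaries (e.g. licensed LIWC category
  lists) passed via `--pos-lexicon` / `--neg-lexicon` or the run config.

## Command line

```bash
# generate a synthetic corpus (chart CSV + bag-of-words + ground truth
# + lexicon files matching the synthetic vocabulary)
lyricbias simulate --seed 1 --out runs/sim

# clean and normalise a real corpus
lyricbias prepare --chart-csv billboard.csv --out prepared.csv

# build a design table / fit one model
lyricbias design --chart-csv prepared.csv --polarity negative --out design.csv
lyricbias fit --chart-csv prepared.csv --polarity negative \
    --effects success,prestige,unbiased,rank --seed 42 --out summary.csv

# full pipeline from a YAML config (see tests/test_pipeline.py for the schema)
lyricbias run-all --config config.yaml
lyricbias report --run-dir runs/out
```

A pipeline run directory contains the design CSVs, per-model draws and
coefficient summaries, diagnostics, a WAIC comparison table, trend series
and plot, and a `manifest.json` echoing the configuration and seeds.

## Reproducibility

Every stochastic step takes an explicit seed (`numpy` `SeedSequence`
spawning throughout); the same configuration and seed reproduce identical
draws, summaries and comparison tables.
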