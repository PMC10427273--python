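"""End-to-end orchestration: prepare -> score -> design -> fit -> compare
-> report, from a single configuration, with a reproducible manifest."""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .corpus import (
    Corpus,
    filter_english,
    filter_years,
    read_bow_corpus,
    read_chart_csv,
    resolve_artists,
    write_bow_corpus,
    write_chart_csv,
)
from .compare import compare, waic
from .covariates import DesignConfig, build_design
from .model import ModelSpec, SamplerConfig, fit, summarize
from .sentiment import (
    load_lexicon,
    packaged_lexicon_paths,
    yearly_valence_proportion,
)
from .simulate import SimConfig, simulate_corpus, simulate_neutral, synthetic_lexicon

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run", "MODEL_SETS", "load_run_config"]

# named effect sets mirroring the analysis's model families
MODEL_SETS = {
    "null": (),
    "success": ("success",),
    "prestige": ("prestige",),
    "content": ("rank",),
    "full": ("success", "prestige"),
    "full_content": ("success", "prestige", "rank"),
    "full_unbiased": ("success", "prestige", "unbiased"),
    "full_content_unbiased": ("success", "prestige", "rank", "unbiased"),
}


@dataclass
class RunConfig:
    out_dir: str
    seed: int
    # exactly one of the two input blocks
    chart_csv: str | None = None
    bow_path: str | None = None
    bow_meta_path: str | None = None
    simulation: SimConfig | None = None
    neutral: bool = False
    pos_lexicon: str | None = None
    neg_lexicon: str | None = None
    polarities: tuple[str, ...] = ("positive", "negative")
    models: tuple[str, ...] = ("null", "full", "full_unbiased")
    design: DesignConfig = field(default_factory=DesignConfig)
    groups: tuple[str, ...] = ("artist", "genre", "year")
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    min_songs_per_year: int = 0
    apply_english_filter: bool = False
    trend_stems: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        has_real = self.chart_csv is not None or self.bow_path is not None
        if has_real == (self.simulation is not None):
            raise ValueError("exactly one of real-input paths or a simulation block is required")
        if not self.models:
            raise ValueError("model list must be non-empty")
        for m in self.models:
            if m not in MODEL_SETS:
                raise ValueError(f"unknown model {m!r}; known: {sorted(MODEL_SETS)}")


def load_run_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if "simulation" in raw and raw["simulation"] is not None:
        raw["simulation"] = SimConfig(**raw["simulation"])
    if "design" in raw:
        raw["design"] = DesignConfig(**raw["design"])
    if "sampler" in raw:
        raw["sampler"] = SamplerConfig(**raw["sampler"])
    for key in ("polarities", "models", "groups", "trend_stems"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.time()


def run(config: RunConfig) -> Path:
    """Execute the pipeline; returns the populated run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": _config_echo(config),
        "stages": [],
    }
    try:
        _run_stages(config, out, manifest)
    except Exception as exc:
        manifest["failed_stage"] = manifest["stages"][-1] if manifest["stages"] else "setup"
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(
            f"pipeline failed at stage {manifest['failed_stage']!r}: {exc}"
        ) from exc
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def _config_echo(config: RunConfig) -> dict:
    echo = dataclasses.asdict(config)
    return json.loads(json.dumps(echo, default=str))


def _run_stages(config: RunConfig, out: Path, manifest: dict) -> None:
    manifest["stages"].append("prepare")
    _stage("prepare")
    truth = None
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.simulation.seed)
        corpus, truth = (
            simulate_neutral(sim) if config.neutral else simulate_corpus(sim)
        )
        chart_corpus = corpus
        lexicon = synthetic_lexicon(sim)
        write_chart_csv(corpus, out / "corpus_chart.csv")
        write_bow_corpus(corpus, out / "corpus_bow.txt", out / "corpus_meta.csv")
        truth.write_json(out / "truth.json")
    else:
        pos_path, neg_path = (
            (config.pos_lexicon, config.neg_lexicon)
            if config.pos_lexicon and config.neg_lexicon
            else packaged_lexicon_paths()
        )
        lexicon = load_lexicon(pos_path, neg_path)
        if config.chart_csv:
            corpus = read_chart_csv(config.chart_csv)
        else:
            corpus = read_bow_corpus(config.bow_path, config.bow_meta_path)
        if config.apply_english_filter:
            corpus = filter_english(corpus)
        if config.min_songs_per_year:
            corpus = filter_years(corpus, config.min_songs_per_year)
        corpus, _ = resolve_artists(corpus)
        chart_corpus = corpus

    manifest["stages"].append("trends")
    _stage("trends")
    for polarity in config.polarities:
        series = yearly_valence_proportion(corpus, lexicon, polarity)
        series.write_csv(out / f"trend_{polarity}.csv")
    for stem in config.trend_stems:
        from .sentiment import yearly_word_frequency

        yearly_word_frequency(corpus, stem).write_csv(out / f"trend_word_{stem}.csv")
    _plot_trends(config, out)

    rng = np.random.SeedSequence(config.seed)
    for polarity in config.polarities:
        manifest["stages"].append(f"design:{polarity}")
        _stage(f"design:{polarity}")
        design = build_design(corpus, chart_corpus, lexicon, polarity, config.design)
        design.write_csv(out / f"design_{polarity}.csv")

        fits = {}
        for model_name in config.models:
            effects = MODEL_SETS[model_name]
            if "rank" in effects and not design.has_rank:
                logger.info("skipping model %s for %s: no ranks", model_name, polarity)
                continue
            if polarity == "positive" and "rank" in effects:
                continue  # content bias applies to negative lyrics only
            manifest["stages"].append(f"fit:{polarity}:{model_name}")
            _stage(f"fit:{polarity}:{model_name}")
            spec = ModelSpec(
                polarity=polarity,
                effects=effects,
                groups=config.groups,
                sampler=config.sampler,
            )
            seed = int(rng.spawn(1)[0].generate_state(1)[0])
            result = fit(spec, design, seed=seed)
            fits[model_name] = result
            _write_fit(result, out / f"fit_{polarity}_{model_name}")

        manifest["stages"].append(f"compare:{polarity}")
        _stage(f"compare:{polarity}")
        if fits:
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                table = compare(
                    [waic(f.loglik_matrix) for f in fits.values()], list(fits)
                )
            table.write_csv(out / f"comparison_{polarity}.csv")
            manifest[f"best_model_{polarity}"] = table.best
            manifest[f"comparison_caveat_{polarity}"] = table.caveat


def _write_fit(result, directory: Path) -> None:
    import pandas as pd

    directory.mkdir(parents=True, exist_ok=True)
    w = waic(result.loglik_matrix)
    (directory / "waic.json").write_text(
        json.dumps(
            {"lppd": w.lppd, "p_waic": w.p_waic, "waic": w.waic, "se": w.se},
            indent=1,
        )
    )
    pd.DataFrame({"pointwise": w.pointwise}).to_csv(
        directory / "waic_pointwise.csv", index=False
    )
    scalars = {
        name: arr.reshape(-1)
        for name, arr in result.posterior.items()
        if arr.ndim == 2
    }
    pd.DataFrame(scalars).to_csv(directory / "draws.csv", index=False)
    summaries = summarize(result)
    pd.DataFrame(
        [dataclasses.asdict(s) for s in summaries]
    ).to_csv(directory / "summary.csv", index=False)
    (directory / "diagnostics.json").write_text(
        json.dumps(
            {
                "diagnostics": result.diagnostics,
                "sampler_info": result.sampler_info,
                "seed": result.seed,
                "groups_used": list(result.groups_used),
            },
            indent=1,
        )
    )
    spec = result.spec
    (directory / "spec.json").write_text(
        json.dumps(
            {
                "polarity": spec.polarity,
                "effects": list(spec.effects),
                "groups": list(spec.groups),
                "priors": dataclasses.asdict(spec.priors),
                "sampler": dataclasses.asdict(spec.sampler),
            },
            indent=1,
        )
    )


def _plot_trends(config: RunConfig, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    fig, ax = plt.subplots(figsize=(7, 4))
    for polarity in config.polarities:
        df = pd.read_csv(out / f"trend_{polarity}.csv")
        ax.plot(df["year"], df["value"], marker="o", ms=3, label=polarity)
    ax.set_xlabel("year")
    ax.set_ylabel("proportion of words")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "trends.svg")
    plt.close(fig)
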