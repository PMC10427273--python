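"""Lagged transmission-bias covariates and design assembly.

For a song released in year *t* and a lag window of ``window`` years:

* ``success``  — mean per-song polarity word count of the ``top_k``
  highest-ranked chart songs of each of years t-1 … t-window;
* ``prestige`` — mean over chart songs by roster ("prestigious") artists
  in the same window;
* ``unbiased`` — mean over *all* songs of the target corpus in the window.

Success and prestige always come from the ranked chart corpus; unbiased
comes from the corpus being modelled.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .corpus import Corpus
from .sentiment import Lexicon, Polarity, score_song

logger = logging.getLogger(__name__)

__all__ = [
    "PrestigeRoster",
    "DesignRow",
    "Design",
    "DesignConfig",
    "WindowError",
    "prestigious_artists",
    "success_covariate",
    "prestige_covariate",
    "unbiased_covariate",
    "build_design",
]


class WindowError(ValueError):
    """A required lag year is absent from the covariate source corpus."""

    def __init__(self, year: int):
        super().__init__(f"lag year {year} absent from covariate source corpus")
        self.year = year


@dataclass(frozen=True)
class PrestigeRoster:
    """Artist units with strictly more than ``threshold`` chart entries."""

    artists: frozenset[str]
    threshold: int
    source: str = ""

    def __contains__(self, unit: str) -> bool:
        return unit in self.artists

    def __len__(self) -> int:
        return len(self.artists)


def prestigious_artists(chart_corpus: Corpus, min_appearances: int = 10) -> PrestigeRoster:
    """Tally chart appearances per artist unit; keep counts > threshold.

    Every credited unit of an occasional collaboration receives an
    appearance.
    """
    counts: Counter[str] = Counter()
    for song in chart_corpus:
        for unit in song.artist_units:
            counts[unit] += 1
    roster = frozenset(u for u, n in counts.items() if n > min_appearances)
    logger.info(
        "prestigious_artists: %d of %d units appear more than %d times",
        len(roster), len(counts), min_appearances,
    )
    return PrestigeRoster(roster, min_appearances, source=chart_corpus.provenance)


def _lag_years(year: int, window: int) -> list[int]:
    return [year - lag for lag in range(1, window + 1)]


def _polarity_count(song, lexicon: Lexicon, polarity: Polarity, proportion: bool) -> float:
    counts = score_song(song, lexicon)
    k = counts.k(polarity)
    return k / counts.W if proportion else float(k)


def success_covariate(
    chart_corpus: Corpus,
    lexicon: Lexicon,
    year: int,
    polarity: Polarity,
    window: int = 3,
    top_k: int = 10,
    proportion: bool = False,
) -> float:
    """Mean polarity word count of the top-``top_k`` songs of each of the
    preceding ``window`` chart years."""
    values: list[float] = []
    years_present = chart_corpus.years
    for lag_year in _lag_years(year, window):
        if lag_year not in years_present:
            raise WindowError(lag_year)
        songs = [
            s for s in chart_corpus.by_year(lag_year)
            if s.rank is not None and s.rank <= top_k
        ]
        values.extend(_polarity_count(s, lexicon, polarity, proportion) for s in songs)
    return float(np.mean(values))


def prestige_covariate(
    chart_corpus: Corpus,
    roster: PrestigeRoster,
    lexicon: Lexicon,
    year: int,
    polarity: Polarity,
    window: int = 3,
    proportion: bool = False,
) -> float | None:
    """Mean polarity word count of roster-artist songs in the window;
    ``None`` (logged) when the window holds no prestigious song."""
    values: list[float] = []
    years_present = chart_corpus.years
    for lag_year in _lag_years(year, window):
        if lag_year not in years_present:
            raise WindowError(lag_year)
        for s in chart_corpus.by_year(lag_year):
            if any(u in roster for u in s.artist_units):
                values.append(_polarity_count(s, lexicon, polarity, proportion))
    if not values:
        logger.info("prestige_covariate: no prestigious songs in window before %d", year)
        return None
    return float(np.mean(values))


def unbiased_covariate(
    corpus: Corpus,
    lexicon: Lexicon,
    year: int,
    polarity: Polarity,
    window: int = 3,
    proportion: bool = False,
) -> float:
    """Mean polarity word count of all songs in the preceding window."""
    values: list[float] = []
    years_present = corpus.years
    for lag_year in _lag_years(year, window):
        if lag_year not in years_present:
            raise WindowError(lag_year)
        values.extend(
            _polarity_count(s, lexicon, polarity, proportion)
            for s in corpus.by_year(lag_year)
        )
    return float(np.mean(values))


@dataclass(frozen=True)
class DesignRow:
    """One model-ready record: response counts, covariates, groupings."""

    song_id: str
    k: int
    W: int
    success: float
    prestige: float
    unbiased: float
    rank: float | None
    artist_idx: int
    genre_idx: int | None
    year_idx: int

    def covariate(self, name: str) -> float:
        value = getattr(self, name)
        if value is None:
            raise ValueError(f"covariate {name!r} missing on row {self.song_id}")
        return float(value)


@dataclass
class DesignConfig:
    window: int = 3
    top_k: int = 10
    prestige_threshold: int = 10
    # "zscore" (default), "center" (subtract mean, keep raw scale), "none"
    scaling: Literal["zscore", "center", "none"] = "zscore"
    proportion: bool = False
    include_rank: bool | None = None  # None: auto (negative polarity + ranks present)
    drop_empty: bool = True  # exclude songs with W == 0


@dataclass
class Design:
    """Assembled design: rows plus level maps and scaling metadata."""

    rows: list[DesignRow]
    polarity: Polarity
    artist_levels: list[str]
    genre_levels: list[str]
    year_levels: list[int]
    config: DesignConfig
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)
    raw_covariates: dict[str, dict[int, float]] = field(default_factory=dict)

    @property
    def has_genre(self) -> bool:
        return len(self.genre_levels) > 0

    @property
    def has_rank(self) -> bool:
        return all(r.rank is not None for r in self.rows) and len(self.rows) > 0

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "song_id": [r.song_id for r in self.rows],
                "k": [r.k for r in self.rows],
                "W": [r.W for r in self.rows],
                "success": [r.success for r in self.rows],
                "prestige": [r.prestige for r in self.rows],
                "unbiased": [r.unbiased for r in self.rows],
                "rank": [r.rank for r in self.rows],
                "artist_idx": [r.artist_idx for r in self.rows],
                "genre_idx": [r.genre_idx for r in self.rows],
                "year_idx": [r.year_idx for r in self.rows],
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _transform(values: np.ndarray, mode: str) -> tuple[np.ndarray, tuple[float, float]]:
    mean = float(np.mean(values))
    if mode == "none":
        return values, (0.0, 1.0)
    if mode == "center":
        return values - mean, (mean, 1.0)
    sd = float(np.std(values))
    if sd == 0.0:
        raise ValueError("cannot z-score a constant covariate column")
    return (values - mean) / sd, (mean, sd)


def build_design(
    target_corpus: Corpus,
    chart_corpus: Corpus,
    lexicon: Lexicon,
    polarity: Polarity,
    config: DesignConfig | None = None,
) -> Design:
    """Assemble one row per target song whose year has a complete lag
    window.

    Success and prestige are computed from ``chart_corpus``; unbiased
    from ``target_corpus`` itself.  Rows whose window holds no
    prestigious song are dropped (logged).  Covariates (and rank, when
    included) are scaled according to ``config.scaling``.
    """
    cfg = config or DesignConfig()
    roster = prestigious_artists(chart_corpus, cfg.prestige_threshold)

    chart_years = chart_corpus.years
    target_years = target_corpus.years
    usable_years = sorted(
        y for y in target_years
        if all(ly in chart_years for ly in _lag_years(y, cfg.window))
        and all(ly in target_years for ly in _lag_years(y, cfg.window))
    )

    per_year: dict[int, tuple[float, float | None, float]] = {}
    for y in usable_years:
        s_val = success_covariate(
            chart_corpus, lexicon, y, polarity, cfg.window, cfg.top_k, cfg.proportion
        )
        p_val = prestige_covariate(
            chart_corpus, roster, lexicon, y, polarity, cfg.window, cfg.proportion
        )
        u_val = unbiased_covariate(
            target_corpus, lexicon, y, polarity, cfg.window, cfg.proportion
        )
        per_year[y] = (s_val, p_val, u_val)

    dropped_prestige = [y for y, (_, p, _) in per_year.items() if p is None]
    if dropped_prestige:
        logger.info(
            "build_design: dropping years with empty prestige window: %s",
            dropped_prestige,
        )
    years_kept = [y for y in usable_years if per_year[y][1] is not None]

    songs = [
        s for s in target_corpus
        if s.year in years_kept and (s.W >= 1 or not cfg.drop_empty)
    ]
    n_empty = sum(1 for s in target_corpus if s.year in years_kept and s.W == 0)
    if n_empty and cfg.drop_empty:
        logger.info("build_design: excluded %d songs with W=0", n_empty)
    if not songs:
        raise ValueError("zero usable design rows")

    include_rank = cfg.include_rank
    if include_rank is None:
        include_rank = polarity == "negative" and all(
            s.rank is not None for s in songs
        )
    if include_rank and any(s.rank is None for s in songs):
        raise ValueError("include_rank requested but some songs lack a rank")

    artist_levels = sorted({s.artist_unit for s in songs})
    genre_levels = sorted({s.genre for s in songs if s.genre is not None})
    year_levels = sorted({s.year for s in songs})
    a_idx = {a: i for i, a in enumerate(artist_levels)}
    g_idx = {g: i for i, g in enumerate(genre_levels)}
    y_idx = {y: i for i, y in enumerate(year_levels)}

    raw = {
        "success": np.array([per_year[s.year][0] for s in songs], dtype=float),
        "prestige": np.array([per_year[s.year][1] for s in songs], dtype=float),
        "unbiased": np.array([per_year[s.year][2] for s in songs], dtype=float),
    }
    if include_rank:
        raw["rank"] = np.array([float(s.rank) for s in songs])

    scaled: dict[str, np.ndarray] = {}
    scaling: dict[str, tuple[float, float]] = {}
    for name, values in raw.items():
        scaled[name], scaling[name] = _transform(values, cfg.scaling)

    rows = [
        DesignRow(
            song_id=s.song_id,
            k=score_song(s, lexicon).k(polarity),
            W=s.W,
            success=float(scaled["success"][i]),
            prestige=float(scaled["prestige"][i]),
            unbiased=float(scaled["unbiased"][i]),
            rank=float(scaled["rank"][i]) if include_rank else None,
            artist_idx=a_idx[s.artist_unit],
            genre_idx=g_idx[s.genre] if s.genre is not None else None,
            year_idx=y_idx[s.year],
        )
        for i, s in enumerate(songs)
    ]
    raw_by_year = {
        "success": {y: per_year[y][0] for y in years_kept},
        "prestige": {y: per_year[y][1] for y in years_kept},
        "unbiased": {y: per_year[y][2] for y in years_kept},
    }
    logger.info(
        "build_design(%s): %d rows over years %d-%d (%d artists, %d genres)",
        polarity, len(rows), min(year_levels), max(year_levels),
        len(artist_levels), len(genre_levels),
    )
    return Design(
        rows=rows,
        polarity=polarity,
        artist_levels=artist_levels,
        genre_levels=genre_levels,
        year_levels=year_levels,
        config=cfg,
        scaling=scaling,
        raw_covariates=raw_by_year,
    )
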