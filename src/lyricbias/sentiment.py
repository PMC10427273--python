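"""Lexicon-based valence coding.

Each word of each song is classified as positive, negative or neither
against two stem lists.  Lexicon entries may end in ``*``, which matches
any stem beginning with the given prefix; matching is resolved to
exact-stem lookups by expanding patterns against a vocabulary, so
scoring stays O(1) per stem.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Literal, Mapping

from ._porter import PorterStemmer
from .corpus import Corpus, Song

logger = logging.getLogger(__name__)

__all__ = [
    "Lexicon",
    "LexiconError",
    "SentimentCounts",
    "TrendSeries",
    "load_lexicon",
    "packaged_lexicon_paths",
    "score_song",
    "score_corpus",
    "yearly_word_frequency",
    "yearly_valence_proportion",
]

Polarity = Literal["positive", "negative"]


class LexiconError(ValueError):
    """Malformed or inconsistent lexicon input."""


@dataclass
class Lexicon:
    """Two disjoint stem pattern sets.

    ``pos_exact``/``neg_exact`` are exact stems; ``pos_prefix``/
    ``neg_prefix`` are wildcard prefixes (the ``*`` already removed).
    """

    pos_exact: frozenset[str]
    neg_exact: frozenset[str]
    pos_prefix: tuple[str, ...] = ()
    neg_prefix: tuple[str, ...] = ()
    source: str = ""
    _cache: dict[str, int] = field(default_factory=dict, repr=False)

    @property
    def n_positive(self) -> int:
        return len(self.pos_exact) + len(self.pos_prefix)

    @property
    def n_negative(self) -> int:
        return len(self.neg_exact) + len(self.neg_prefix)

    def classify(self, stem: str) -> int:
        """1 if positive, -1 if negative, 0 if neither."""
        try:
            return self._cache[stem]
        except KeyError:
            pass
        if stem in self.pos_exact or any(stem.startswith(p) for p in self.pos_prefix):
            out = 1
        elif stem in self.neg_exact or any(stem.startswith(p) for p in self.neg_prefix):
            out = -1
        else:
            out = 0
        self._cache[stem] = out
        return out

    def expand(self, vocabulary: Iterable[str]) -> "Lexicon":
        """Resolve wildcard patterns into exact stems over a vocabulary."""
        vocab = list(vocabulary)
        pos = set(self.pos_exact)
        neg = set(self.neg_exact)
        for stem in vocab:
            for p in self.pos_prefix:
                if stem.startswith(p):
                    pos.add(stem)
            for p in self.neg_prefix:
                if stem.startswith(p):
                    neg.add(stem)
        clash = pos & neg
        if clash:
            raise LexiconError(
                f"stems match both polarities after expansion: {sorted(clash)[:5]}"
            )
        return Lexicon(frozenset(pos), frozenset(neg), source=self.source)


def _read_patterns(path: Path, stemmer: Callable[[str], str]) -> tuple[set[str], set[str]]:
    """Return (exact stems, prefix patterns) from one lexicon file."""
    exact: set[str] = set()
    prefix: set[str] = set()
    for line in path.read_text(encoding="utf-8").splitlines():
        entry = line.split("#", 1)[0].strip().lower()
        if not entry:
            continue
        if entry.endswith("*"):
            # wildcard prefixes are kept verbatim: stemming a truncated
            # form is not meaningful
            prefix.add(entry[:-1])
        else:
            exact.add(stemmer(entry))
    return exact, prefix


def load_lexicon(
    pos_path: str | Path,
    neg_path: str | Path,
    stemmer: Callable[[str], str] | None = None,
) -> Lexicon:
    """Load positive/negative stem lists (one pattern per line, ``#``
    comments, optional trailing ``*`` wildcard).

    Non-wildcard entries are stemmed with the corpus stemmer and
    deduplicated.  Any overlap between the two lists is an error.
    """
    stemmer = stemmer or PorterStemmer()
    pos_path, neg_path = Path(pos_path), Path(neg_path)
    pos_exact, pos_prefix = _read_patterns(pos_path, stemmer)
    neg_exact, neg_prefix = _read_patterns(neg_path, stemmer)

    overlap = (pos_exact & neg_exact) | (pos_prefix & neg_prefix)
    for p in pos_prefix:
        overlap |= {e for e in neg_exact if e.startswith(p)}
    for p in neg_prefix:
        overlap |= {e for e in pos_exact if e.startswith(p)}
    for a in pos_prefix:
        for b in neg_prefix:
            if a.startswith(b) or b.startswith(a):
                overlap |= {a, b}
    if overlap:
        raise LexiconError(
            f"entries present in both polarities: {sorted(overlap)[:5]}"
        )
    lex = Lexicon(
        frozenset(pos_exact),
        frozenset(neg_exact),
        tuple(sorted(pos_prefix)),
        tuple(sorted(neg_prefix)),
        source=f"{pos_path.name}+{neg_path.name}",
    )
    logger.info(
        "load_lexicon: %d positive, %d negative patterns", lex.n_positive, lex.n_negative
    )
    return lex


def packaged_lexicon_paths() -> tuple[Path, Path]:
    """Paths of the small open placeholder lexicon shipped for testing."""
    data = Path(__file__).parent / "data"
    return data / "positive_stems.txt", data / "negative_stems.txt"


@dataclass(frozen=True)
class SentimentCounts:
    """Binomial sufficient statistics for one song."""

    song_id: str
    k_pos: int
    k_neg: int
    W: int

    def __post_init__(self) -> None:
        if not (0 <= self.k_pos and 0 <= self.k_neg and self.k_pos + self.k_neg <= self.W):
            raise ValueError(
                f"invalid counts k_pos={self.k_pos} k_neg={self.k_neg} W={self.W}"
            )

    def k(self, polarity: Polarity) -> int:
        return self.k_pos if polarity == "positive" else self.k_neg


def score_song(song: Song, lexicon: Lexicon) -> SentimentCounts:
    """Count positive and negative words in one song's bag."""
    k_pos = k_neg = 0
    for stem, cnt in song.bag.items():
        cls = lexicon.classify(stem)
        if cls > 0:
            k_pos += cnt
        elif cls < 0:
            k_neg += cnt
    return SentimentCounts(song.song_id, k_pos, k_neg, song.W)


def score_corpus(corpus: Corpus, lexicon: Lexicon) -> dict[str, SentimentCounts]:
    return {s.song_id: score_song(s, lexicon) for s in corpus}


@dataclass
class TrendSeries:
    """A year-indexed series with a denominator convention tag."""

    values: dict[int, float]
    denominator: str = "proportion-of-year-words"

    def __getitem__(self, year: int) -> float:
        return self.values[year]

    def years(self) -> list[int]:
        return sorted(self.values)

    def to_rows(self) -> list[tuple[int, float]]:
        return [(y, self.values[y]) for y in self.years()]

    def write_csv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("year,value\n")
            for y, v in self.to_rows():
                fh.write(f"{y},{v!r}\n")


def _year_totals(corpus: Corpus) -> dict[int, list[Song]]:
    out: dict[int, list[Song]] = {}
    for s in corpus:
        out.setdefault(s.year, []).append(s)
    return out


def yearly_word_frequency(corpus: Corpus, stem: str) -> TrendSeries:
    """Per-year proportion of one stem out of all words of that year."""
    values: dict[int, float] = {}
    for year, songs in _year_totals(corpus).items():
        total_w = sum(s.W for s in songs)
        if total_w == 0:
            logger.warning("yearly_word_frequency: year %d has zero words, omitted", year)
            continue
        count = sum(s.bag.get(stem, 0) for s in songs)
        values[year] = count / total_w
    return TrendSeries(values, denominator="proportion-of-year-words")


def yearly_valence_proportion(
    corpus: Corpus, lexicon: Lexicon, polarity: Polarity
) -> TrendSeries:
    """Per-year proportion of positive (or negative) words."""
    values: dict[int, float] = {}
    for year, songs in _year_totals(corpus).items():
        total_w = sum(s.W for s in songs)
        if total_w == 0:
            logger.warning(
                "yearly_valence_proportion: year %d has zero words, omitted", year
            )
            continue
        k = sum(score_song(s, lexicon).k(polarity) for s in songs)
        values[year] = k / total_w
    return TrendSeries(values, denominator="proportion-of-year-words")
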