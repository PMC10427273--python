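"""Corpus ingestion and normalisation.

Reads the two supported corpus dialects — a chart CSV (one row per
ranked song with raw lyric text) and a sparse bag-of-words file with a
sidecar metadata table — into a single :class:`Song` / :class:`Corpus`
representation, and implements the cleaning filters applied before
modelling: an English heuristic, a per-year minimum-size filter, artist
name clustering and collaboration splitting.
"""

from __future__ import annotations

import csv
import logging
import re
import unicodedata
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from ._porter import PorterStemmer

logger = logging.getLogger(__name__)

__all__ = [
    "Song",
    "Corpus",
    "ArtistIndex",
    "CorpusFormatError",
    "RowError",
    "tokenize_and_stem",
    "detect_english",
    "read_chart_csv",
    "write_chart_csv",
    "read_bow_corpus",
    "write_bow_corpus",
    "filter_years",
    "filter_english",
    "cluster_artist_names",
    "split_collaborations",
    "normalize_artist_name",
    "resolve_artists",
]


class CorpusFormatError(ValueError):
    """A corpus file does not conform to its declared dialect."""


class RowError(ValueError):
    """A single record could not be parsed; carries the row index."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


@dataclass
class Song:
    """One track with its stem-count bag.

    ``artist_units`` holds every credited artist unit (length one except
    for occasional collaborations between known solo artists); the first
    entry is the lead artist, used for model grouping.
    """

    song_id: str
    title: str
    artist_units: tuple[str, ...]
    year: int
    bag: dict[str, int]
    genre: str | None = None
    rank: int | None = None
    raw_artist: str | None = None

    @property
    def artist_unit(self) -> str:
        return self.artist_units[0]

    @property
    def W(self) -> int:
        return sum(self.bag.values())

    def __post_init__(self) -> None:
        if self.rank is not None and not (1 <= self.rank <= 100):
            raise ValueError(f"rank {self.rank} outside [1, 100]")
        if any(c < 0 for c in self.bag.values()):
            raise ValueError("negative bag count")


@dataclass
class Corpus:
    songs: list[Song]
    provenance: str = "unknown"

    def __post_init__(self) -> None:
        counts = Counter(s.song_id for s in self.songs)
        if len(counts) != len(self.songs):
            dup = next(i for i, n in counts.items() if n > 1)
            raise ValueError(f"duplicate song_id {dup!r}")

    @property
    def years(self) -> set[int]:
        return {s.year for s in self.songs}

    def by_year(self, year: int) -> list[Song]:
        return [s for s in self.songs if s.year == year]

    def __len__(self) -> int:
        return len(self.songs)

    def __iter__(self):
        return iter(self.songs)

    @property
    def vocabulary(self) -> set[str]:
        vocab: set[str] = set()
        for s in self.songs:
            vocab.update(s.bag)
        return vocab


_TOKEN_RE = re.compile(r"[a-z0-9']+")


def tokenize_and_stem(
    text: str, stemmer: Callable[[str], str] | None = None
) -> Counter[str]:
    """Lowercase, strip punctuation, stem each token, count stems.

    Tokens containing digits are kept as-is apart from lowercasing.
    Empty text yields an empty bag.
    """
    stemmer = stemmer or PorterStemmer()
    bag: Counter[str] = Counter()
    for tok in _TOKEN_RE.findall(text.lower()):
        tok = tok.strip("'")
        if not tok:
            continue
        bag[stemmer(tok)] += 1
    return bag


def detect_english(bag: Mapping[str, int]) -> bool:
    """Heuristic language check: the stem ``the`` occurs at least once."""
    return bag.get("the", 0) >= 1


# ---------------------------------------------------------------------------
# chart CSV dialect

DEFAULT_CHART_COLUMNS = {
    "rank": "Rank",
    "title": "Song",
    "artist": "Artist",
    "year": "Year",
    "lyrics": "Lyrics",
}


def read_chart_csv(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    stemmer: Callable[[str], str] | None = None,
) -> Corpus:
    """Read a ranked-chart corpus (one row per song, raw lyric text).

    Lyrics are passed through :func:`tokenize_and_stem`; genre is absent
    from this dialect and left missing.  Songs whose lyrics stem to an
    empty bag are kept here (W = 0) and excluded downstream.
    """
    colmap = dict(DEFAULT_CHART_COLUMNS)
    if columns:
        colmap.update(columns)
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for role, name in colmap.items():
            if name not in header:
                raise CorpusFormatError(
                    f"missing mandatory column {name!r} (role: {role})"
                )
        songs: list[Song] = []
        for i, row in enumerate(reader):
            try:
                rank = int(row[colmap["rank"]])
                year = int(row[colmap["year"]])
            except (TypeError, ValueError) as exc:
                raise RowError(i, f"non-integer rank/year: {exc}") from None
            bag = dict(tokenize_and_stem(row[colmap["lyrics"]] or "", stemmer))
            raw_artist = (row[colmap["artist"]] or "").strip()
            songs.append(
                Song(
                    song_id=f"chart-{year}-{rank:03d}-{i}",
                    title=row[colmap["title"]] or "",
                    artist_units=(normalize_artist_name(raw_artist),),
                    year=year,
                    bag=bag,
                    rank=rank,
                    raw_artist=raw_artist,
                )
            )
    n_empty = sum(1 for s in songs if s.W == 0)
    if n_empty:
        logger.info("read_chart_csv: %d songs with empty bags (W=0), "
                    "flagged for downstream exclusion", n_empty)
    logger.info("read_chart_csv: %d songs from %s", len(songs), path)
    return Corpus(songs, provenance="chart")


def write_chart_csv(corpus: Corpus, path: str | Path) -> None:
    """Serialize a ranked corpus in the chart dialect.

    The bag is written as a space-joined pseudo-lyric (each stem repeated
    by its count) so that a read/stem round trip reproduces the bag;
    this holds because stems are fixed points for the tokenizer.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["Rank", "Song", "Artist", "Year", "Lyrics"])
        for s in corpus:
            lyric = " ".join(
                " ".join([stem] * cnt) for stem, cnt in sorted(s.bag.items())
            )
            writer.writerow(
                [s.rank, s.title, s.raw_artist or s.artist_unit, s.year, lyric]
            )


# ---------------------------------------------------------------------------
# bag-of-words dialect ('#' comments, '%' vocabulary line, 1-based indices)


def read_bow_corpus(
    bow_path: str | Path,
    meta_path: str | Path,
) -> Corpus:
    """Read a sparse bag-of-words corpus plus its metadata table.

    The bow file holds ``#`` comment lines, one ``%``-prefixed
    comma-separated vocabulary line (1-based indexing), then per-track
    lines ``trackID,mxmID,idx:cnt,...``.  Metadata is a CSV with columns
    ``track_id,artist,year,genre``.  Tracks missing from the metadata or
    lacking a year or artist are dropped (logged).
    """
    bow_path, meta_path = Path(bow_path), Path(meta_path)

    meta: dict[str, dict[str, str]] = {}
    with meta_path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"track_id", "artist", "year", "genre"}
        if not required <= set(reader.fieldnames or []):
            missing = required - set(reader.fieldnames or [])
            raise CorpusFormatError(f"metadata missing columns {sorted(missing)}")
        for row in reader:
            meta[row["track_id"]] = row

    vocab: list[str] | None = None
    songs: list[Song] = []
    seen: set[str] = set()
    n_no_meta = n_no_year_artist = 0
    with bow_path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith("%"):
                vocab = line[1:].split(",")
                continue
            if vocab is None:
                raise CorpusFormatError(
                    f"line {lineno}: track line before vocabulary line"
                )
            parts = line.split(",")
            if len(parts) < 2:
                raise CorpusFormatError(f"line {lineno}: malformed track line")
            track_id = parts[0]
            if track_id in seen:
                raise CorpusFormatError(f"line {lineno}: duplicate track ID {track_id!r}")
            seen.add(track_id)
            bag: dict[str, int] = {}
            for pair in parts[2:]:
                if not pair:
                    continue
                idx_s, _, cnt_s = pair.partition(":")
                idx, cnt = int(idx_s), int(cnt_s)
                if not (1 <= idx <= len(vocab)):
                    raise CorpusFormatError(
                        f"line {lineno}: word index {idx} outside vocabulary "
                        f"of size {len(vocab)}"
                    )
                stem = vocab[idx - 1]
                bag[stem] = bag.get(stem, 0) + cnt
            m = meta.get(track_id)
            if m is None:
                n_no_meta += 1
                continue
            if not m["year"].strip() or not m["artist"].strip():
                n_no_year_artist += 1
                continue
            raw_artist = m["artist"].strip()
            rank_field = (m.get("rank") or "").strip()
            songs.append(
                Song(
                    song_id=track_id,
                    title=m.get("title", "") or "",
                    artist_units=(normalize_artist_name(raw_artist),),
                    year=int(m["year"]),
                    bag=bag,
                    genre=m["genre"].strip() or None,
                    rank=int(rank_field) if rank_field else None,
                    raw_artist=raw_artist,
                )
            )
    logger.info(
        "read_bow_corpus: kept %d tracks (%d without metadata, "
        "%d without year/artist)", len(songs), n_no_meta, n_no_year_artist,
    )
    return Corpus(songs, provenance="bow")


def write_bow_corpus(
    corpus: Corpus, bow_path: str | Path, meta_path: str | Path
) -> None:
    """Serialize a corpus in the bag-of-words dialect plus metadata CSV."""
    vocab = sorted(corpus.vocabulary)
    index = {stem: i + 1 for i, stem in enumerate(vocab)}
    with Path(bow_path).open("w", encoding="utf-8") as fh:
        fh.write("# bag-of-words corpus\n")
        fh.write("%" + ",".join(vocab) + "\n")
        for s in corpus:
            pairs = ",".join(
                f"{index[stem]}:{cnt}" for stem, cnt in sorted(s.bag.items())
            )
            fh.write(f"{s.song_id},{s.song_id}," + pairs + "\n")
    with Path(meta_path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["track_id", "artist", "year", "genre", "title", "rank"])
        for s in corpus:
            writer.writerow(
                [
                    s.song_id,
                    s.raw_artist or s.artist_unit,
                    s.year,
                    s.genre or "",
                    s.title,
                    "" if s.rank is None else s.rank,
                ]
            )


# ---------------------------------------------------------------------------
# filters


def filter_years(corpus: Corpus, min_songs: int = 500) -> Corpus:
    """Keep only years with strictly more than ``min_songs`` songs."""
    counts = Counter(s.year for s in corpus)
    keep = {y for y, n in counts.items() if n > min_songs}
    songs = [s for s in corpus if s.year in keep]
    logger.info(
        "filter_years(min_songs=%d): %d -> %d songs, %d -> %d years",
        min_songs, len(corpus), len(songs), len(counts), len(keep),
    )
    return Corpus(songs, provenance=corpus.provenance)


def filter_english(corpus: Corpus) -> Corpus:
    """Drop songs failing the ``the``-presence English heuristic."""
    songs = [s for s in corpus if detect_english(s.bag)]
    logger.info("filter_english: %d -> %d songs", len(corpus), len(songs))
    return Corpus(songs, provenance=corpus.provenance)


# ---------------------------------------------------------------------------
# artist normalisation

_PUNCT_RE = re.compile(r"[^\w\s]", re.UNICODE)
_WS_RE = re.compile(r"\s+")


def _strip_accents(text: str) -> str:
    return "".join(
        c for c in unicodedata.normalize("NFKD", text)
        if not unicodedata.combining(c)
    )


def normalize_artist_name(name: str) -> str:
    """Canonical surface form: lowercase, accent/punctuation-stripped,
    whitespace-collapsed, token order preserved."""
    name = _strip_accents(name.lower())
    name = _PUNCT_RE.sub(" ", name)
    return _WS_RE.sub(" ", name).strip()


def _fingerprint(name: str) -> str:
    return " ".join(sorted(normalize_artist_name(name).split()))


@dataclass
class ArtistIndex:
    """Raw-name to artist-unit mapping built by fingerprint clustering."""

    mapping: dict[str, str] = field(default_factory=dict)
    solo_set: set[str] = field(default_factory=set)
    collaborations: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def resolve(self, name: str) -> str:
        if name in self.mapping:
            return self.mapping[name]
        return normalize_artist_name(name)

    @property
    def units(self) -> set[str]:
        return set(self.mapping.values())


def cluster_artist_names(names: Sequence[str]) -> ArtistIndex:
    """Cluster raw artist strings by fingerprint key collision.

    The fingerprint lowercases, strips accents and punctuation, collapses
    whitespace and sorts tokens.  Every raw name sharing a fingerprint
    maps to one unit whose canonical form is the normalised spelling of
    the most frequent raw variant (ties broken lexicographically on the
    raw string).
    """
    if any(not n for n in names):
        raise ValueError("empty artist name")
    freq = Counter(names)
    clusters: dict[str, list[str]] = {}
    for name in names:
        clusters.setdefault(_fingerprint(name), []).append(name)
    mapping: dict[str, str] = {}
    for fp, members in clusters.items():
        canonical_raw = min(set(members), key=lambda n: (-freq[n], n))
        unit = normalize_artist_name(canonical_raw)
        for m in members:
            mapping[m] = unit
    return ArtistIndex(mapping=mapping)


# separator tokens; "and" matches only the two listed spellings, the
# others match lowercase-only (whole-token), and "," always splits.
_CASE_SENSITIVE_SEPARATORS = {"and", "AND"}
_LOWER_SEPARATORS = {"featuring", "feat.", "feat", "with"}


def _split_on_separators(name: str) -> list[str]:
    parts: list[str] = []
    current: list[str] = []
    for chunk in name.split(","):
        for tok in chunk.split():
            if tok in _CASE_SENSITIVE_SEPARATORS or tok.lower() in _LOWER_SEPARATORS and tok == tok.lower():
                if current:
                    parts.append(" ".join(current))
                    current = []
            else:
                current.append(tok)
        if current:
            parts.append(" ".join(current))
            current = []
    return [p for p in parts if p.strip()]


def split_collaborations(
    name: str, solo_set: Iterable[str], index: ArtistIndex | None = None
) -> list[str]:
    """Resolve a raw artist string into one or more artist units.

    No separator: one solo unit.  Separators with every part a known
    solo unit: the list of solo units (occasional collaboration).
    Otherwise: a single stable-collaboration unit for the whole string.
    """
    if not name or not name.strip():
        raise ValueError("empty artist name")
    solo = set(solo_set)
    resolve = index.resolve if index is not None else normalize_artist_name
    parts = _split_on_separators(name)
    if len(parts) <= 1:
        return [resolve(name)]
    units = [resolve(p) for p in parts]
    if all(u in solo for u in units):
        return units
    return [normalize_artist_name(name)]


def resolve_artists(corpus: Corpus) -> tuple[Corpus, ArtistIndex]:
    """Cluster all raw artist names in a corpus and split collaborations.

    Returns a corpus whose songs carry resolved ``artist_units`` plus the
    index used.  The solo set is built from names containing no
    separator, after clustering.
    """
    raw = [s.raw_artist or s.artist_unit for s in corpus]
    index = cluster_artist_names(raw)
    solo_set = {
        index.resolve(n) for n in raw if len(_split_on_separators(n)) <= 1
    }
    index.solo_set = solo_set
    songs = []
    for s in corpus:
        name = s.raw_artist or s.artist_unit
        units = tuple(split_collaborations(name, solo_set, index))
        if len(units) > 1:
            index.collaborations[normalize_artist_name(name)] = units
        songs.append(replace(s, artist_units=units))
    logger.info(
        "resolve_artists: %d raw names -> %d units (%d solo, %d occasional collaborations)",
        len(set(raw)), len({u for s in songs for u in s.artist_units}),
        len(solo_set), len(index.collaborations),
    )
    return Corpus(songs, provenance=corpus.provenance), index
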