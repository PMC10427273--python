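import numpy as np
import pytest

from lyricbias.corpus import Corpus, Song
from lyricbias.sentiment import Lexicon


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_lexicon():
    """Exact-stem lexicon for hand-checkable scoring."""
    return Lexicon(
        pos_exact=frozenset({"love", "happi"}),
        neg_exact=frozenset({"hate", "sad"}),
        source="toy",
    )


def make_song(song_id, year, bag, artist="artist-a", rank=None, genre=None):
    return Song(
        song_id=song_id,
        title=song_id,
        artist_units=(artist,),
        year=year,
        bag=dict(bag),
        genre=genre,
        rank=rank,
    )


@pytest.fixture
def song_factory():
    return make_song


@pytest.fixture
def chart_csv(tmp_path):
    path = tmp_path / "chart.csv"
    path.write_text(
        "Rank,Song,Artist,Year,Lyrics\n"
        '1,First,Madonna,1990,"love love you"\n'
        '2,Second,Prince,1990,"hate the rain"\n',
        encoding="utf-8",
    )
    return path


def make_yearly_corpus(years, songs_per_year, bag_fn, provenance="chart", ranked=True):
    """Deterministic corpus builder: bag_fn(year, i) -> bag."""
    songs = []
    for year in years:
        for i in range(songs_per_year):
            songs.append(
                Song(
                    song_id=f"{year}-{i:03d}",
                    title=f"{year}-{i}",
                    artist_units=(f"artist-{i % 5}",),
                    year=year,
                    bag=bag_fn(year, i),
                    rank=(i + 1) if ranked and i < 100 else None,
                )
            )
    return Corpus(songs, provenance=provenance)


@pytest.fixture
def yearly_corpus_factory():
    return make_yearly_corpus
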