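import numpy as np
import pytest

from bwsnorms import design as dz
from bwsnorms import pipeline as pl
from bwsnorms import synthetic_world as sw


@pytest.fixture(scope="session")
def fixtures():
    """The packaged toy study (lexicon, taxonomy, judgments, mapping)."""
    return pl.make_fixtures(seed=0)


@pytest.fixture(scope="session")
def small_world():
    """A 100-word latent world with the default correlation structure."""
    return sw.sample_world(100, seed=7)


@pytest.fixture(scope="session")
def attentive_study(small_world):
    """Design + low-noise simulated judgments over the small world."""
    lexicon = [dz.WordItem(w) for w in small_world.words]
    tuple_set = dz.generate_tuples(lexicon, k=4, factor=2, seed=8)
    raters = sw.make_raters(50, noise_sd=0.05, careless_rate=0.0, seed=9)
    judgments = sw.simulate_judgments(tuple_set, small_world, raters, per_tuple=10, seed=10)
    return tuple_set, judgments


def brute_force_bws(judgment_rows, tuple_items):
    """Independent tally oracle for BWS raw scores.

    ``judgment_rows`` is a list of (tuple_id, best, worst) triples.
    """
    best: dict = {}
    worst: dict = {}
    appearances: dict = {}
    for tuple_id, b, w in judgment_rows:
        for word in tuple_items[tuple_id]:
            appearances[word] = appearances.get(word, 0) + 1
        best[b] = best.get(b, 0) + 1
        worst[w] = worst.get(w, 0) + 1
    return {
        word: (best.get(word, 0) - worst.get(word, 0)) / n
        for word, n in appearances.items()
    }
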