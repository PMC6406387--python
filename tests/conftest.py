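import numpy as np
import pytest

from sensory_axes.epq import default_epq_map
from sensory_axes.profile import QUADRANTS, ResponseSet, default_item_map, default_norms


@pytest.fixture(scope="session")
def item_map():
    return default_item_map()


@pytest.fixture(scope="session")
def epq_map():
    return default_epq_map()


@pytest.fixture(scope="session")
def norms():
    return default_norms()


def make_responses(item_map, per_quadrant_rating, pid="P001"):
    """ResponseSet with a constant rating per quadrant."""
    ratings = {i: per_quadrant_rating[q] for i, q in item_map.entries.items()}
    return ResponseSet(participant_id=pid, ratings=ratings)


@pytest.fixture(scope="session")
def uniform_responses(item_map):
    def _make(rating, pid="P001"):
        return make_responses(item_map, {q: rating for q in QUADRANTS}, pid)

    return _make
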