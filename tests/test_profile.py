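"""Quadrant scoring, normative categorization, axis scores and derived
quadrants of the 60-item sensory-profile instrument."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sensory_axes.profile import (
    ACTIVE_QUADRANTS,
    HIGH_THRESHOLD_QUADRANTS,
    QUADRANTS,
    AxisScores,
    ItemMap,
    NormativeTable,
    ProfileValidationError,
    ResponseSet,
    axis_groups,
    axis_scores,
    categorize,
    derived_quadrant,
    highest_quadrant,
    score_quadrants,
)

from conftest import make_responses

ratings_strategy = st.lists(st.integers(1, 5), min_size=60, max_size=60)


def responses_from_list(item_map, values):
    return ResponseSet("P", dict(zip(item_map.entries, values)))


# -- score_quadrants -------------------------------------------------------

@pytest.mark.parametrize(
    "per_quadrant, expected",
    [
        ({q: 1 for q in QUADRANTS}, {q: 15 for q in QUADRANTS}),
        ({q: 5 for q in QUADRANTS}, {q: 75 for q in QUADRANTS}),
        (
            {"seeking": 4, "avoiding": 2, "low_registration": 1, "sensitivity": 3},
            {"seeking": 60, "avoiding": 30, "low_registration": 15, "sensitivity": 45},
        ),
    ],
)
def test_quadrant_sums(item_map, per_quadrant, expected):
    raw = score_quadrants(make_responses(item_map, per_quadrant), item_map)
    assert raw == expected


def test_missing_rating_names_the_item(item_map, uniform_responses):
    resp = uniform_responses(3)
    broken = ResponseSet("P001", {k: v for k, v in resp.ratings.items() if k != "item_017"})
    with pytest.raises(ProfileValidationError, match="item_017"):
        score_quadrants(broken, item_map)


@pytest.mark.parametrize("bad", [0, 6, 2.5, "3"])
def test_out_of_range_rating_rejected(item_map, uniform_responses, bad):
    ratings = dict(uniform_responses(3).ratings)
    ratings["item_030"] = bad
    with pytest.raises(ProfileValidationError, match="item_030"):
        score_quadrants(ResponseSet("P001", ratings), item_map)


def test_item_map_structure_enforced():
    with pytest.raises(ProfileValidationError):
        ItemMap({f"i{k}": "seeking" for k in range(60)})  # 60 items, one quadrant
    with pytest.raises(ProfileValidationError):
        ItemMap({f"i{k}": QUADRANTS[k % 4] for k in range(59)})  # 59 items


# -- categorize ------------------------------------------------------------

@pytest.mark.parametrize(
    "raw, expected",
    [
        (30, "similar"),   # z = 0
        (41, "much_more"), # z = 2.2
        (22, "less"),      # z = -1.6
        (35, "similar"),   # z = 1, inner-inclusive boundary
        (40, "more"),      # z = 2, inner-inclusive boundary
        (20, "less"),      # z = -2
        (19, "much_less"), # z = -2.2
    ],
)
def test_normative_categories(raw, expected):
    norms = NormativeTable({q: (30.0, 5.0) for q in QUADRANTS})
    cats = categorize({q: raw for q in QUADRANTS}, norms)
    assert all(c == expected for c in cats.values())


def test_nonpositive_sd_rejected():
    with pytest.raises(ProfileValidationError):
        NormativeTable({q: (30.0, 0.0) for q in QUADRANTS})


def test_categorize_monotone_in_raw_score(norms):
    order = ["much_less", "less", "similar", "more", "much_more"]
    prev = 0
    for raw in range(15, 76):
        cat = categorize({q: raw for q in QUADRANTS}, norms)["seeking"]
        assert order.index(cat) >= prev
        prev = order.index(cat)


# -- axis scores -----------------------------------------------------------

def test_axis_scores_zero_at_floor(item_map, uniform_responses):
    assert axis_scores(uniform_responses(1), item_map) == AxisScores(0, 0)


def test_axis_scores_reach_extremes(item_map):
    active_max = make_responses(
        item_map, {"seeking": 5, "avoiding": 5, "low_registration": 1, "sensitivity": 1}
    )
    assert axis_scores(active_max, item_map).br == 120
    high_max = make_responses(
        item_map, {"seeking": 5, "low_registration": 5, "sensitivity": 1, "avoiding": 1}
    )
    assert axis_scores(high_max, item_map).t == 120


def test_axis_scores_hand_example(item_map):
    resp = make_responses(
        item_map, {"seeking": 4, "avoiding": 2, "low_registration": 1, "sensitivity": 2}
    )
    assert axis_scores(resp, item_map) == AxisScores(br=45, t=15)


@settings(derandomize=True, max_examples=60)
@given(values=ratings_strategy)
def test_axis_decomposition_against_per_item_sum(item_map, values):
    """br and t equal signed per-item sums of the rescaled ratings."""
    resp = responses_from_list(item_map, values)
    br = t = 0
    for item, rating in resp.ratings.items():
        quad = item_map.entries[item]
        br += (rating - 1) * (1 if quad in ACTIVE_QUADRANTS else -1)
        t += (rating - 1) * (1 if quad in HIGH_THRESHOLD_QUADRANTS else -1)
    assert axis_scores(resp, item_map) == AxisScores(br, t)


@settings(derandomize=True, max_examples=40)
@given(values=ratings_strategy)
def test_rating_reversal_negates_axes(item_map, values):
    """r -> 6 - r mirrors the 0-4 rescale about 2, flipping both axes."""
    a = axis_scores(responses_from_list(item_map, values), item_map)
    b = axis_scores(responses_from_list(item_map, [6 - v for v in values]), item_map)
    assert (b.br, b.t) == (-a.br, -a.t)


@settings(derandomize=True, max_examples=20)
@given(values=ratings_strategy, seed=st.integers(0, 2**16))
def test_axis_scores_item_order_invariant(item_map, values, seed):
    resp = responses_from_list(item_map, values)
    rng = np.random.default_rng(seed)
    shuffled_items = list(resp.ratings)
    rng.shuffle(shuffled_items)
    shuffled = ResponseSet("P", {i: resp.ratings[i] for i in shuffled_items})
    assert axis_scores(shuffled, item_map) == axis_scores(resp, item_map)


# -- derived quadrant / highest quadrant -----------------------------------

@pytest.mark.parametrize(
    "br, t, expected",
    [
        (45, 15, "seeking"),
        (-5, 3, "low_registration"),
        (-5, -3, "sensitivity"),
        (5, -3, "avoiding"),
        (0, 10, "unclassified"),
        (10, 0, "unclassified"),
        (0, 0, "unclassified"),
    ],
)
def test_derived_quadrant(br, t, expected):
    assert derived_quadrant(AxisScores(br, t)) == expected


@pytest.mark.parametrize(
    "raw, quadrant, tie",
    [
        ({"seeking": 60, "avoiding": 30, "low_registration": 15, "sensitivity": 45}, "seeking", False),
        ({"seeking": 50, "avoiding": 20, "low_registration": 50, "sensitivity": 15}, None, True),
        ({"seeking": 15, "avoiding": 16, "low_registration": 15, "sensitivity": 15}, "avoiding", False),
    ],
)
def test_highest_quadrant(raw, quadrant, tie):
    res = highest_quadrant(raw)
    assert (res.quadrant, res.tie) == (quadrant, tie)


@pytest.mark.parametrize(
    "quadrant, groups",
    [
        ("low_registration", ("passive", "high")),
        ("seeking", ("active", "high")),
        ("sensitivity", ("passive", "low")),
        ("avoiding", ("active", "low")),
    ],
)
def test_axis_groups(quadrant, groups):
    assert axis_groups(quadrant) == groups


def test_axis_groups_rejects_unclassified():
    with pytest.raises(ValueError):
        axis_groups("unclassified")


@settings(derandomize=True, max_examples=40)
@given(
    target=st.sampled_from(QUADRANTS),
    on=st.lists(st.integers(4, 5), min_size=15, max_size=15),
    off=st.lists(st.integers(1, 2), min_size=45, max_size=45),
)
def test_archetypes_agree_across_classifiers(item_map, target, on, off):
    """On archetype respondents (on-target items >= 4, others <= 2) the
    derived quadrant matches the highest-raw-score quadrant."""
    ratings = {}
    on_iter, off_iter = iter(on), iter(off)
    for item, quad in item_map.entries.items():
        ratings[item] = next(on_iter) if quad == target else next(off_iter)
    resp = ResponseSet("P", ratings)
    hq = highest_quadrant(score_quadrants(resp, item_map))
    assert hq.quadrant == target and not hq.tie
    assert derived_quadrant(axis_scores(resp, item_map)) == target
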