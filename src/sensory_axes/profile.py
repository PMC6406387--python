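"""Scoring of a 60-item, four-quadrant sensory-profile questionnaire.

The instrument has 15 Likert items (rated 1-5) per quadrant of the
two-axis model of sensory processing.  The two axes are:

* **behavioral response (BR)** -- passive (low registration, sensitivity)
  versus active (seeking, avoiding) response strategies;
* **neurological threshold (T)** -- low (sensitivity, avoiding) versus
  high (low registration, seeking) thresholds for responding to stimuli.

Raw quadrant sums are compared to a normative mean/SD table; signed axis
scores are built by rescaling each rating to 0-4, negating the passive
(resp. low-threshold) item sums and totalling, which places every
respondent on a point (BR, T) in [-120, 120]^2 whose sign pattern yields
a *derived quadrant*.

The commercial instrument's item texts and normative values are not
distributed here: the item map and the normative table are user-supplied
configuration, with a synthetic default layout for simulation and tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, NamedTuple, Optional, Tuple

QUADRANTS: Tuple[str, ...] = ("low_registration", "seeking", "sensitivity", "avoiding")

#: quadrants on the passive side of the behavioral-response axis
PASSIVE_QUADRANTS = frozenset({"low_registration", "sensitivity"})
#: quadrants on the active side of the behavioral-response axis
ACTIVE_QUADRANTS = frozenset({"seeking", "avoiding"})
#: quadrants on the high side of the threshold axis
HIGH_THRESHOLD_QUADRANTS = frozenset({"low_registration", "seeking"})
#: quadrants on the low side of the threshold axis
LOW_THRESHOLD_QUADRANTS = frozenset({"sensitivity", "avoiding"})

CATEGORIES: Tuple[str, ...] = ("much_less", "less", "similar", "more", "much_more")

ITEMS_PER_QUADRANT = 15
N_ITEMS = 60
RATING_MIN, RATING_MAX = 1, 5


class ProfileValidationError(ValueError):
    """A response set or configuration violates the instrument's structure."""


@dataclass(frozen=True)
class ItemMap:
    """Assignment of the 60 item ids to the four quadrants (15 each)."""

    entries: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.entries) != N_ITEMS:
            raise ProfileValidationError(
                f"item map must contain exactly {N_ITEMS} items, got {len(self.entries)}"
            )
        counts: Dict[str, int] = {q: 0 for q in QUADRANTS}
        for item, quad in self.entries.items():
            if quad not in counts:
                raise ProfileValidationError(f"item {item!r}: unknown quadrant {quad!r}")
            counts[quad] += 1
        for quad, n in counts.items():
            if n != ITEMS_PER_QUADRANT:
                raise ProfileValidationError(
                    f"quadrant {quad!r} has {n} items, expected {ITEMS_PER_QUADRANT}"
                )

    def items_for(self, quadrant: str) -> Tuple[str, ...]:
        return tuple(i for i, q in self.entries.items() if q == quadrant)


@dataclass(frozen=True)
class ResponseSet:
    """One participant's integer Likert answers (item id -> 1..5)."""

    participant_id: str
    ratings: Mapping[str, int]


@dataclass(frozen=True)
class NormativeTable:
    """Per-quadrant normative mean and standard deviation (score points)."""

    values: Mapping[str, Tuple[float, float]]

    def __post_init__(self) -> None:
        for quad in QUADRANTS:
            if quad not in self.values:
                raise ProfileValidationError(f"normative table missing quadrant {quad!r}")
            _, sd = self.values[quad]
            if not sd > 0:
                raise ProfileValidationError(f"normative sd for {quad!r} must be > 0, got {sd}")


class AxisScores(NamedTuple):
    """Signed axis scores: ``br`` (passive < 0 < active), ``t`` (low < 0 < high)."""

    br: int
    t: int


class HighestQuadrant(NamedTuple):
    quadrant: Optional[str]
    tie: bool


def default_item_map() -> ItemMap:
    """Synthetic 60-item layout: items 1-15 low_registration, 16-30 seeking,
    31-45 sensitivity, 46-60 avoiding.  Stands in for the copyrighted
    instrument's layout; same 60/15 structure."""
    entries = {}
    for i in range(N_ITEMS):
        entries[f"item_{i + 1:03d}"] = QUADRANTS[i // ITEMS_PER_QUADRANT]
    return ItemMap(entries)


def default_norms(mean: float = 45.0, sd: float = 8.0) -> NormativeTable:
    """Synthetic normative table (midpoint mean, plausible spread) for tests
    and simulation; real use requires the published normative values."""
    return NormativeTable({q: (mean, sd) for q in QUADRANTS})


def _validated_rating(responses: ResponseSet, item: str) -> int:
    try:
        r = responses.ratings[item]
    except KeyError:
        raise ProfileValidationError(
            f"participant {responses.participant_id!r}: missing rating for {item!r}"
        ) from None
    if not isinstance(r, (int,)) or isinstance(r, bool) or not RATING_MIN <= r <= RATING_MAX:
        raise ProfileValidationError(
            f"participant {responses.participant_id!r}: rating for {item!r} is {r!r}, "
            f"expected an integer in [{RATING_MIN}, {RATING_MAX}]"
        )
    return r


def score_quadrants(responses: ResponseSet, item_map: ItemMap) -> Dict[str, int]:
    """Sum the 15 raw ratings of each quadrant's items.

    Returns a dict quadrant -> raw score in [15, 75].  Raises
    :class:`ProfileValidationError` naming the offending item on missing or
    out-of-range ratings.
    """
    sums = {q: 0 for q in QUADRANTS}
    for item, quad in item_map.entries.items():
        sums[quad] += _validated_rating(responses, item)
    return sums


def categorize(raw: Mapping[str, int], norms: NormativeTable) -> Dict[str, str]:
    """Classify each quadrant raw score against the normative distribution.

    The z score (raw - mean)/sd maps to five bands: ``similar`` for
    |z| <= 1, ``less``/``more`` for 1 < |z| <= 2, ``much_less``/``much_more``
    beyond two standard deviations.  Boundaries are inclusive on the inner
    side (z = 1 is still ``similar``).
    """
    out = {}
    for quad in QUADRANTS:
        mean, sd = norms.values[quad]
        z = (raw[quad] - mean) / sd
        if abs(z) <= 1:
            cat = "similar"
        elif z > 2:
            cat = "much_more"
        elif z > 1:
            cat = "more"
        elif z < -2:
            cat = "much_less"
        else:
            cat = "less"
        out[quad] = cat
    return out


def rescaled_quadrant_sums(responses: ResponseSet, item_map: ItemMap) -> Dict[str, int]:
    """Per-quadrant sums of ratings rescaled to 0-4 (rating minus one)."""
    sums = {q: 0 for q in QUADRANTS}
    for item, quad in item_map.entries.items():
        sums[quad] += _validated_rating(responses, item) - 1
    return sums


def axis_scores(responses: ResponseSet, item_map: ItemMap) -> AxisScores:
    """Derive the signed behavioral-response and threshold axis scores.

    Each rating is rescaled to 0-4 (avoiding a gap in the distribution);
    passive-quadrant and low-threshold-quadrant sums are negated, then
    totalled with their active/high counterparts.  Each axis lies in
    [-120, 120] (30 items x 4).
    """
    s = rescaled_quadrant_sums(responses, item_map)
    br = (s["seeking"] + s["avoiding"]) - (s["low_registration"] + s["sensitivity"])
    t = (s["low_registration"] + s["seeking"]) - (s["sensitivity"] + s["avoiding"])
    return AxisScores(br=br, t=t)


def derived_quadrant(axes: AxisScores) -> str:
    """Quadrant implied by the signs of (BR, T).

    (+, +) seeking; (-, +) low_registration; (-, -) sensitivity;
    (+, -) avoiding.  A zero coordinate lies on an axis line, which the
    model does not assign: returns ``"unclassified"``.
    """
    if axes.br == 0 or axes.t == 0:
        return "unclassified"
    if axes.br > 0:
        return "seeking" if axes.t > 0 else "avoiding"
    return "low_registration" if axes.t > 0 else "sensitivity"


def highest_quadrant(raw: Mapping[str, int]) -> HighestQuadrant:
    """Quadrant with the highest raw score; a shared maximum sets ``tie``.

    Tied participants are excluded from quadrant-categorical analyses
    downstream.
    """
    best = max(raw[q] for q in QUADRANTS)
    winners = [q for q in QUADRANTS if raw[q] == best]
    if len(winners) > 1:
        return HighestQuadrant(quadrant=None, tie=True)
    return HighestQuadrant(quadrant=winners[0], tie=False)


def axis_groups(quadrant: str) -> Tuple[str, str]:
    """Map a quadrant to its (BR group, T group) pair.

    low_registration -> (passive, high); seeking -> (active, high);
    sensitivity -> (passive, low); avoiding -> (active, low).
    """
    if quadrant not in QUADRANTS:
        raise ValueError(f"cannot assign axis groups for {quadrant!r}")
    br = "passive" if quadrant in PASSIVE_QUADRANTS else "active"
    t = "high" if quadrant in HIGH_THRESHOLD_QUADRANTS else "low"
    return br, t
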