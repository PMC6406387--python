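"""Scoring of a 24-item brief Eysenck personality questionnaire.

Two 12-item scales: introversion/extraversion (``ie``) and neuroticism.
Two items are reverse-scored.  Ratings (1-5) are reverse-transformed where
marked, rescaled to 0-4, summed per scale (0-48) and shifted by -24 so that
each axis runs from -24 to 24 and crosses zero at the scale midpoint,
mirroring the axis-crossing of the four-quadrant personality model.

Which items load on which scale, and which two are reversed, is published
with the instrument and is therefore user-supplied configuration; the
default map is an arbitrary fixed assignment with the same 24/12/2
structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Mapping, NamedTuple, Tuple

SCALES: Tuple[str, str] = ("ie", "neuroticism")
N_ITEMS = 24
ITEMS_PER_SCALE = 12
N_REVERSE = 2
SCALE_SHIFT = 24


class EPQValidationError(ValueError):
    pass


@dataclass(frozen=True)
class EPQItemMap:
    """Item-to-scale assignment plus the reverse-scored item set."""

    entries: Mapping[str, str]
    reverse_items: FrozenSet[str]

    def __post_init__(self) -> None:
        if len(self.entries) != N_ITEMS:
            raise EPQValidationError(f"expected {N_ITEMS} items, got {len(self.entries)}")
        counts = {s: 0 for s in SCALES}
        for item, scale in self.entries.items():
            if scale not in counts:
                raise EPQValidationError(f"item {item!r}: unknown scale {scale!r}")
            counts[scale] += 1
        for scale, n in counts.items():
            if n != ITEMS_PER_SCALE:
                raise EPQValidationError(f"scale {scale!r} has {n} items, expected {ITEMS_PER_SCALE}")
        if not set(self.reverse_items) <= set(self.entries):
            raise EPQValidationError("reverse_items contains unknown item ids")
        if len(self.reverse_items) != N_REVERSE:
            raise EPQValidationError(
                f"instrument has exactly {N_REVERSE} reverse-scored items, "
                f"got {len(self.reverse_items)}"
            )


class EPQAxisScores(NamedTuple):
    ie: int
    neuroticism: int


def default_epq_map() -> EPQItemMap:
    """Fixed synthetic assignment: odd items -> ie, even -> neuroticism;
    items 2 and 3 reverse-scored."""
    entries = {f"epq_{i:02d}": ("ie" if i % 2 == 1 else "neuroticism") for i in range(1, N_ITEMS + 1)}
    return EPQItemMap(entries=entries, reverse_items=frozenset({"epq_02", "epq_03"}))


def score_epq(ratings: Mapping[str, int], item_map: EPQItemMap) -> EPQAxisScores:
    """Score the two scales into signed axis values in [-24, 24].

    Reverse-marked items are transformed r -> 6 - r, every rating rescaled
    to 0-4, summed per scale (range 0-48) and shifted by -24.
    """
    sums: Dict[str, int] = {s: 0 for s in SCALES}
    for item, scale in item_map.entries.items():
        try:
            r = ratings[item]
        except KeyError:
            raise EPQValidationError(f"missing rating for {item!r}") from None
        if not isinstance(r, int) or isinstance(r, bool) or not 1 <= r <= 5:
            raise EPQValidationError(f"rating for {item!r} is {r!r}, expected integer in [1, 5]")
        if item in item_map.reverse_items:
            r = 6 - r
        sums[scale] += r - 1
    return EPQAxisScores(ie=sums["ie"] - SCALE_SHIFT, neuroticism=sums["neuroticism"] - SCALE_SHIFT)
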