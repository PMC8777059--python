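"""Emotion labeling of self-assessment ratings.

Two schemes are supported for rating trials of a photo-prompted
reminiscence conversation:

* the valence--arousal (VA) quadrant mapping, which assigns each trial to
  one of the four classical affect quadrants (happy / frightened / boredom
  / relaxed) or to the axes when either coordinate is zero; and
* the pleasure--stress (PS) rule that replaces arousal with a stress
  rating, yielding a binary positive/negative split with an ``excluded``
  remainder.

The PS rule is: *positive* iff pleasure > 0 and stress <= 1; *negative*
iff pleasure < 0 or stress > 2; anything else is *excluded*.  On the
integer rating grid (pleasure, arousal in -4..4, stress in 1..7) the rule
partitions the 567 cells into 36 positive, 477 negative and 54 excluded.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass

__all__ = [
    "Ratings",
    "EmotionLabel",
    "VAQuadrant",
    "label_ps",
    "va_quadrant",
    "summarize_labels",
    "rating_grid",
    "LabelSummary",
]

PLEASURE_RANGE = range(-4, 5)
AROUSAL_RANGE = range(-4, 5)
STRESS_RANGE = range(1, 8)


class EmotionLabel(str, enum.Enum):
    """Binary PS emotion class with an explicit excluded remainder."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    EXCLUDED = "excluded"


class VAQuadrant(str, enum.Enum):
    """Quadrants of the valence--arousal plane; axis points are separate."""

    HAPPY = "happy"
    FRIGHTENED = "frightened"
    BOREDOM = "boredom"
    RELAXED = "relaxed"
    ON_AXIS = "on_axis"


@dataclass(frozen=True)
class Ratings:
    """One trial's self-assessment: integer pleasure/arousal in [-4, 4],
    stress in [1, 7]."""

    pleasure: int
    arousal: int
    stress: int

    def __post_init__(self) -> None:
        for name, value, rng in (
            ("pleasure", self.pleasure, PLEASURE_RANGE),
            ("arousal", self.arousal, AROUSAL_RANGE),
            ("stress", self.stress, STRESS_RANGE),
        ):
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise TypeError(f"{name} must be an integer, got {value!r}")
            if value not in rng:
                raise ValueError(
                    f"{name}={value} outside allowed range "
                    f"[{rng.start}, {rng.stop - 1}]"
                )


def label_ps(r: Ratings) -> EmotionLabel:
    """Classify a trial under the pleasure/stress rule.

    Positive requires pleasure > 0 *and* stress <= 1 (i.e. stress at the
    scale minimum); negative requires pleasure < 0 *or* stress > 2.  The
    two rules are disjoint; ratings satisfying neither are excluded.
    """
    if r.pleasure > 0 and r.stress <= 1:
        return EmotionLabel.POSITIVE
    if r.pleasure < 0 or r.stress > 2:
        return EmotionLabel.NEGATIVE
    return EmotionLabel.EXCLUDED


def va_quadrant(pleasure: int, arousal: int) -> VAQuadrant:
    """Map (valence, arousal) to its quadrant; either coordinate zero
    lands on the axis, where trials are not distinguishable."""
    if pleasure == 0 or arousal == 0:
        return VAQuadrant.ON_AXIS
    if pleasure > 0:
        return VAQuadrant.HAPPY if arousal > 0 else VAQuadrant.RELAXED
    return VAQuadrant.FRIGHTENED if arousal > 0 else VAQuadrant.BOREDOM


def rating_grid() -> list[Ratings]:
    """Enumerate all 9 x 9 x 7 = 567 rating cells."""
    return [
        Ratings(p, a, s)
        for p, a, s in itertools.product(PLEASURE_RANGE, AROUSAL_RANGE, STRESS_RANGE)
    ]


@dataclass(frozen=True)
class LabelSummary:
    """Class counts under both schemes for one ratings table."""

    n_rows: int
    ps_counts: dict[EmotionLabel, int]
    va_counts: dict[VAQuadrant, int]


def summarize_labels(table) -> LabelSummary:
    """Count PS classes and VA quadrants over a ratings table.

    ``table`` is any iterable of objects with ``pleasure``, ``arousal``
    and ``stress`` attributes (e.g. ``RatingsTable.ratings()`` rows).
    PS counts partition the table; both count dicts sum to its size.
    """
    ps = {label: 0 for label in EmotionLabel}
    va = {quad: 0 for quad in VAQuadrant}
    n = 0
    for row in table:
        r = row if isinstance(row, Ratings) else Ratings(row.pleasure, row.arousal, row.stress)
        ps[label_ps(r)] += 1
        va[va_quadrant(r.pleasure, r.arousal)] += 1
        n += 1
    return LabelSummary(n_rows=n, ps_counts=ps, va_counts=va)
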