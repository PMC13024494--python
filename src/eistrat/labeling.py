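"""Response-driven binarization of 7-point affect ratings.

Participants rate experienced arousal and valence on a 7-point Likert scale
after each stimulus video. Ratings 1-3 map to the low pole (label 0), 5-7 to
the high pole (label 1). The neutral midpoint 4 is retained rather than
dropped: it receives a *weak* label taken from the stimulus quadrant's pole
on that dimension, so every video contributes to both the arousal and the
valence analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

DIMENSIONS = ("arousal", "valence")

#: Binary pole of each stimulus quadrant on each dimension.
#: HAHV = high arousal / high valence, etc.
QUADRANT_POLES: dict[str, dict[str, int]] = {
    "HAHV": {"arousal": 1, "valence": 1},
    "HALV": {"arousal": 1, "valence": 0},
    "LAHV": {"arousal": 0, "valence": 1},
    "LALV": {"arousal": 0, "valence": 0},
}

QUADRANTS = tuple(QUADRANT_POLES)

RESPONSE = "response"
WEAK = "weak"


@dataclass(frozen=True)
class VideoLabel:
    """Binary label for one (video, dimension), with provenance."""

    dimension: str
    label: int  # 0 = low pole, 1 = high pole
    provenance: str  # "response" (from the rating) or "weak" (from quadrant)
    rating: int
    quadrant: str


def binarize_rating(rating: int, dimension: str, quadrant: str) -> VideoLabel:
    """Map one 7-point rating to a binary label.

    Ratings 1-3 -> 0, 5-7 -> 1 (provenance ``"response"``); the neutral
    rating 4 takes the stimulus quadrant's pole on ``dimension``
    (provenance ``"weak"``).
    """
    if dimension not in DIMENSIONS:
        raise ValueError(f"unknown dimension {dimension!r}")
    if quadrant not in QUADRANT_POLES:
        raise ValueError(f"unknown quadrant {quadrant!r}")
    if not (isinstance(rating, (int,)) or float(rating).is_integer()):
        raise ValueError(f"rating must be an integer in 1..7, got {rating!r}")
    rating = int(rating)
    if not 1 <= rating <= 7:
        raise ValueError(f"rating must be in 1..7, got {rating}")

    if rating == 4:
        label, provenance = QUADRANT_POLES[quadrant][dimension], WEAK
    elif rating <= 3:
        label, provenance = 0, RESPONSE
    else:
        label, provenance = 1, RESPONSE
    return VideoLabel(dimension, label, provenance, rating, quadrant)


def label_sessions(ratings: pd.DataFrame) -> pd.DataFrame:
    """Expand a ratings table into one binary label row per (video, dimension).

    Parameters
    ----------
    ratings
        One row per (participant, video) with columns ``participant``,
        ``video``, ``quadrant``, ``arousal_rating``, ``valence_rating``.

    Returns
    -------
    DataFrame with columns participant, video, quadrant, dimension, rating,
    label, provenance — exactly two rows (arousal + valence) per input video;
    neutral ratings are never dropped.
    """
    required = {"participant", "video", "quadrant", "arousal_rating", "valence_rating"}
    missing_cols = required - set(ratings.columns)
    if missing_cols:
        raise ValueError(f"ratings table missing columns: {sorted(missing_cols)}")

    missing = []
    for dim in DIMENSIONS:
        col = f"{dim}_rating"
        bad = ratings.loc[ratings[col].isna(), ["participant", "video"]]
        missing += [(p, v, dim) for p, v in bad.itertuples(index=False)]
    if missing:
        raise ValueError(f"missing ratings for (participant, video, dimension): {missing}")

    rows = []
    for rec in ratings.itertuples(index=False):
        for dim in DIMENSIONS:
            lab = binarize_rating(getattr(rec, f"{dim}_rating"), dim, rec.quadrant)
            rows.append(
                {
                    "participant": rec.participant,
                    "video": rec.video,
                    "quadrant": rec.quadrant,
                    "dimension": dim,
                    "rating": lab.rating,
                    "label": lab.label,
                    "provenance": lab.provenance,
                }
            )
    return pd.DataFrame(rows)
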