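"""Synthetic affect-study cohorts with controllable label–expression consistency.

This module generates every table the downstream analysis consumes, with the
statistical structure the analysis assumes:

* a cohort of participants with emotional-intelligence (EI) scores on the
  0–1200 scale and a latent *consistency* parameter — the probability that a
  facial frame's estimated affect sign agrees with the participant's own
  subjective label — that increases monotonically with EI;
* per-participant sessions: one 7-point arousal and valence rating per
  stimulus video (with a configurable neutral-rating mass at 4) and
  frame-level continuous valence/arousal estimates in [−1, 1] whose sign
  congruence and magnitude distribution follow the consistency parameter;
* an HRV feature table (participant × emotion condition) with an injectable
  EI-group × emotion interaction keyed to a *true* cutoff that is independent
  of the cutoff scanner under test, enabling recovery experiments;
* fixed-length numeric feature vectors per frame whose informative
  coordinates are proportional to the frame's continuous estimates, so class
  separability grows with |estimate| and "ambiguous" frames are intrinsically
  harder.

Every generator is a pure function of (config, seed): identical inputs give
identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig
from .labeling import DIMENSIONS, QUADRANTS, binarize_rating

# Sub-stream tags so each generator draws from its own independent stream.
_COHORT_STREAM = 1
_SESSION_STREAM = 2
_HRV_STREAM = 3
_FEATURE_STREAM = 4

# Sum-to-zero interaction pattern across the four emotion conditions.
_INTERACTION_PATTERN = np.array([1.0, -1.0, 1.0, -1.0])
_EMOTION_PATTERN = np.array([1.0, -0.5, 0.5, -1.0])


@dataclass
class Cohort:
    """A simulated participant sample.

    Attributes
    ----------
    participants
        One row per participant: ``participant`` (unique id), ``ei``
        (score in [0, 1200]), ``consistency`` (congruence probability).
    videos
        One row per (participant, video): ``participant``, ``video``,
        ``quadrant`` — by default one video per circumplex quadrant.
    """

    participants: pd.DataFrame
    videos: pd.DataFrame
    config: SimConfig = field(repr=False, default=None)


def _participant_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"P{i + 1:0{width}d}" for i in range(n)]


def generate_cohort(config: SimConfig) -> Cohort:
    """Draw a cohort of participants with EI scores and consistency parameters.

    EI ~ Normal(ei_mean, ei_sd), clipped to [0, 1200]; the consistency
    parameter is ``config.consistency_map(EI)``. Each participant is assigned
    ``n_videos_per_participant`` stimulus videos cycling through the four
    circumplex quadrants.
    """
    rng = np.random.default_rng([_COHORT_STREAM, config.seed])
    n = config.n_participants
    ids = _participant_ids(n)
    ei = np.clip(rng.normal(config.ei_mean, config.ei_sd, size=n), 0.0, 1200.0)
    consistency = np.array([config.consistency_map(e) for e in ei])
    participants = pd.DataFrame(
        {"participant": ids, "ei": ei, "consistency": consistency}
    )

    vids = []
    for pid in ids:
        for v in range(config.n_videos_per_participant):
            vids.append(
                {
                    "participant": pid,
                    "video": f"V{v + 1}",
                    "quadrant": QUADRANTS[v % len(QUADRANTS)],
                }
            )
    return Cohort(participants=participants, videos=pd.DataFrame(vids), config=config)


def _rating_pmf(pole: int, sd: float) -> np.ndarray:
    """Discretized normal over the non-neutral ratings {1,2,3,5,6,7}.

    Centered at 6 for the high pole, 2 for the low pole; the neutral point 4
    carries its own configured mass and is excluded here.
    """
    center = 6.0 if pole == 1 else 2.0
    pts = np.array([1, 2, 3, 5, 6, 7], dtype=float)
    w = np.exp(-0.5 * ((pts - center) / sd) ** 2)
    return w / w.sum()


def generate_session(participant: pd.Series, config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one participant's ratings table and frame table.

    Ratings: per video and dimension one 7-point rating — neutral (4) with
    probability ``neutral_rating_prob``, otherwise drawn from a discretized
    normal centered on the stimulus quadrant's pole.

    Frames: per frame and dimension a continuous estimate in [−1, 1]. The
    estimate's sign matches the direction of the participant's binary label
    (response-driven; weak for neutral ratings) with probability equal to the
    participant's consistency parameter; |estimate| is Beta-distributed with
    congruent frames stochastically larger than incongruent ones.

    ``participant`` must carry fields ``participant`` (id), ``consistency``;
    deterministic given (config.seed, participant id).
    """
    pid = str(participant["participant"])
    consistency = float(participant["consistency"])
    # Stable per-participant sub-seed from the id's digits.
    p_index = int("".join(c for c in pid if c.isdigit()) or 0)
    rng = np.random.default_rng([_SESSION_STREAM, config.seed, p_index])

    n_videos = config.n_videos_per_participant
    quadrants = [QUADRANTS[v % len(QUADRANTS)] for v in range(n_videos)]

    non_neutral = np.array([1, 2, 3, 5, 6, 7])
    rating_rows = []
    for v, quad in enumerate(quadrants):
        row = {"participant": pid, "video": f"V{v + 1}", "quadrant": quad}
        for dim in DIMENSIONS:
            pole = 1 if quad[0 if dim == "arousal" else 2] == "H" else 0
            if rng.random() < config.neutral_rating_prob:
                rating = 4
            else:
                rating = int(rng.choice(non_neutral, p=_rating_pmf(pole, config.rating_sd)))
            row[f"{dim}_rating"] = rating
        rating_rows.append(row)
    ratings = pd.DataFrame(rating_rows)

    mp = config.magnitude_params
    frame_rows = []
    for row in rating_rows:
        video, quad = row["video"], row["quadrant"]
        nf = config.frames_per_video
        frame = {"participant": pid, "video": video, "frame": np.arange(nf)}
        for dim in DIMENSIONS:
            label = binarize_rating(row[f"{dim}_rating"], dim, quad).label
            direction = 1.0 if label == 1 else -1.0
            congruent = rng.random(nf) < consistency
            mag = np.where(
                congruent,
                rng.beta(mp.congruent.a, mp.congruent.b, size=nf),
                rng.beta(mp.incongruent.a, mp.incongruent.b, size=nf),
            )
            frame[f"{dim}_est"] = np.where(congruent, direction, -direction) * mag
        frame["valid"] = True
        frame_rows.append(pd.DataFrame(frame))
    frames = pd.concat(frame_rows, ignore_index=True)
    return ratings, frames


def generate_sessions(cohort: Cohort, config: SimConfig | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate and stack the ratings and frame tables for a whole cohort."""
    config = config or cohort.config
    ratings, frames = [], []
    for _, prow in cohort.participants.iterrows():
        r, f = generate_session(prow, config)
        ratings.append(r)
        frames.append(f)
    return pd.concat(ratings, ignore_index=True), pd.concat(frames, ignore_index=True)


def hrv_columns(config: SimConfig) -> list[str]:
    return [f"hrv_{i + 1:02d}" for i in range(config.n_hrv_vars)]


def generate_hrv_table(cohort: Cohort, config: SimConfig | None = None) -> pd.DataFrame:
    """Generate the participant × emotion-condition HRV feature table.

    Each variable v follows a two-way cell-means structure::

        value = baseline_v + group_effect·g + emotion_effect·e_c
                + hrv_effect_v · g · i_c + Normal(0, hrv_noise_sd)

    where g = ±0.5 codes the *true* EI grouping (EI > ``hrv_true_cutoff``),
    e_c is a fixed emotion pattern and i_c a sum-to-zero interaction contrast
    over the four conditions. ``hrv_effect`` = 0 gives a null interaction.
    """
    config = config or cohort.config
    if config.n_hrv_vars == 0:
        raise ValueError("n_hrv_vars must be positive to generate an HRV table")
    rng = np.random.default_rng([_HRV_STREAM, config.seed])
    effects = config.hrv_effects()
    cols = hrv_columns(config)

    part = cohort.participants
    g = np.where(part["ei"].to_numpy() > config.hrv_true_cutoff, 0.5, -0.5)

    rows = []
    for i, pid in enumerate(part["participant"]):
        for c, cond in enumerate(QUADRANTS):
            row = {"participant": pid, "condition": cond}
            for v, col in enumerate(cols):
                mean = (
                    0.1 * v
                    + config.hrv_group_effect * g[i]
                    + config.hrv_emotion_effect * _EMOTION_PATTERN[c]
                    + effects[v] * g[i] * _INTERACTION_PATTERN[c]
                )
                row[col] = mean + rng.normal(0.0, config.hrv_noise_sd)
            rows.append(row)
    return pd.DataFrame(rows)


def feature_columns(config: SimConfig) -> list[str]:
    d = 2 * config.n_informative_per_dim + config.n_noise_features
    return [f"f{i:02d}" for i in range(d)]


def _loadings(k: int) -> np.ndarray:
    # Fixed, sign-alternating, slowly decaying loadings.
    return np.array([(-1.0) ** j * (1.0 - 0.15 * j) for j in range(k)])


def generate_features(frames: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Derive a fixed-length feature vector for every frame.

    The first ``n_informative_per_dim`` coordinates load on the frame's
    continuous arousal estimate, the next block on the valence estimate, each
    plus Normal(0, feature_noise_sd) noise; the remaining coordinates are
    pure standard-normal noise. Separability of the binary labels therefore
    scales with |estimate| relative to the noise floor.
    """
    rng = np.random.default_rng([_FEATURE_STREAM, config.seed])
    n = len(frames)
    k = config.n_informative_per_dim
    w = _loadings(k)
    blocks = []
    for dim in DIMENSIONS:
        est = frames[f"{dim}_est"].to_numpy()[:, None]
        blocks.append(est * w[None, :] + rng.normal(0.0, config.feature_noise_sd, size=(n, k)))
    if config.n_noise_features:
        blocks.append(rng.standard_normal((n, config.n_noise_features)))
    X = np.hstack(blocks)
    out = frames[["participant", "video", "frame"]].copy()
    for j, col in enumerate(feature_columns(config)):
        out[col] = X[:, j]
    return out
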