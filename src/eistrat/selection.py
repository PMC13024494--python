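"""Consistency-based frame selection and leakage-safe participant partitioning.

Training data are curated in two stages per video: (1) keep frames whose
estimated affect sign agrees with the video-level subjective label
(congruence filter); (2) among those, take the top-k frames by |arousal
estimate| and the top-k by |valence estimate| (k = 100 by default), giving
2k frames per video and videos × 2k per participant when supply allows.

Evaluation uses a fixed test set of 2 High-EI + 2 Low-EI participants; the
remaining participants are split 8:2 into train/validation at the
participant level (stratified on participant-majority labels), so no
participant's frames cross partitions. From the *unfiltered* test-participant
frame pool, two matched test strata are drawn per affect dimension: an
*unambiguous* subset (sign-congruent, large |estimate|) and an *ambiguous*
subset (sign-incongruent or small |estimate|), six frames per video each.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SelectionConfig
from .labeling import DIMENSIONS


class PartitionError(ValueError):
    """Raised when group sizes cannot support the requested partition."""


@dataclass
class SplitSpec:
    """Participant-level partition plus derived test-subset frame ids."""

    train: list[str]
    val: list[str]
    test: list[str]
    test_by_group: dict[str, list[str]] = field(default_factory=dict)
    # dimension -> list of frame ids, filled in by the pipeline
    baseline_frames: dict[str, list[str]] = field(default_factory=dict)
    unambiguous_frames: dict[str, list[str]] = field(default_factory=dict)
    ambiguous_frames: dict[str, list[str]] = field(default_factory=dict)

    def validate(self, all_participants=None) -> None:
        parts = [set(self.train), set(self.val), set(self.test)]
        if parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2]:
            raise PartitionError("train/val/test participant sets overlap")
        if all_participants is not None:
            union = parts[0] | parts[1] | parts[2]
            if union != set(all_participants):
                raise PartitionError("partition does not cover all participants")
        for dim in self.unambiguous_frames:
            ua = set(self.unambiguous_frames[dim])
            am = set(self.ambiguous_frames.get(dim, []))
            if ua & am:
                raise PartitionError(f"unambiguous/ambiguous overlap for {dim}")

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SplitSpec":
        return cls(**json.loads(text))


def frame_ids(frames: pd.DataFrame) -> pd.Series:
    """Canonical frame identifier ``participant:video:frame``."""
    return (
        frames["participant"].astype(str)
        + ":"
        + frames["video"].astype(str)
        + ":"
        + frames["frame"].astype(str)
    )


def _with_direction(frames: pd.DataFrame, labels: pd.DataFrame, dimension: str) -> pd.DataFrame:
    lab = labels[labels["dimension"] == dimension][["participant", "video", "label"]]
    merged = (
        frames.reset_index(names="_idx")
        .merge(lab, on=["participant", "video"], how="left", validate="m:1")
        .set_index("_idx")
        .rename_axis(frames.index.name)
    )
    if merged["label"].isna().any():
        bad = merged.loc[merged["label"].isna(), ["participant", "video"]].drop_duplicates()
        raise ValueError(f"missing {dimension} labels for videos: {bad.to_records(index=False)}")
    merged["direction"] = np.where(merged["label"] == 1, 1.0, -1.0)
    return merged


def congruence_filter(frames: pd.DataFrame, labels: pd.DataFrame, dimension: str) -> pd.DataFrame:
    """Keep frames whose estimate sign matches the video label direction.

    An estimate of exactly 0 has no sign and is excluded. Frames flagged
    invalid (``valid`` = False) are dropped first.
    """
    if "valid" in frames.columns:
        frames = frames[frames["valid"]]
    merged = _with_direction(frames, labels, dimension)
    est = merged[f"{dimension}_est"].to_numpy()
    keep = np.sign(est) == merged["direction"].to_numpy()
    return frames.loc[merged.index[keep]]


def select_top_frames(
    frames: pd.DataFrame, labels: pd.DataFrame, config: SelectionConfig
) -> pd.DataFrame:
    """Two-stage selection: congruence filter, then top-k magnitude per dimension.

    Per video, the union of the top-k arousal-congruent frames by |arousal
    estimate| and the top-k valence-congruent frames by |valence estimate| is
    taken. If overlap leaves the union short of 2k, next-ranked frames are
    appended alternately from each dimension's congruent list until 2k is
    reached or both lists are exhausted (then a shortfall warning is issued).
    Magnitude ties break toward the lower frame index.
    """
    k = config.k_per_dimension
    ranked: dict[str, dict[tuple, list[int]]] = {}
    for dim in DIMENSIONS:
        cong = congruence_filter(frames, labels, dim).copy()
        cong["_mag"] = cong[f"{dim}_est"].abs()
        cong = cong.sort_values(["_mag", "frame"], ascending=[False, True], kind="mergesort")
        ranked[dim] = {key: grp.index.to_list() for key, grp in cong.groupby(["participant", "video"], sort=False)}

    videos = frames[["participant", "video"]].drop_duplicates()
    selected: list[int] = []
    shortfalls = []
    for key in videos.itertuples(index=False, name=None):
        lists = {dim: ranked[dim].get(key, []) for dim in DIMENSIONS}
        if all(len(v) == 0 for v in lists.values()):
            warnings.warn(f"video {key} has no congruent frames on either dimension")
            continue
        chosen: list[int] = []
        in_set: set[int] = set()
        for dim in DIMENSIONS:
            for idx in lists[dim][:k]:
                if idx not in in_set:
                    in_set.add(idx)
                    chosen.append(idx)
        # Backfill overlap losses alternately from each dimension's remainder.
        rest = {dim: iter(lists[dim][k:]) for dim in DIMENSIONS}
        exhausted = {dim: False for dim in DIMENSIONS}
        while len(chosen) < 2 * k and not all(exhausted.values()):
            for dim in DIMENSIONS:
                if len(chosen) >= 2 * k:
                    break
                for idx in rest[dim]:
                    if idx not in in_set:
                        in_set.add(idx)
                        chosen.append(idx)
                        break
                else:
                    exhausted[dim] = True
        if len(chosen) < 2 * k:
            shortfalls.append((key, len(chosen)))
        selected.extend(chosen)
    if shortfalls:
        warnings.warn(f"selection shortfall (video, frames available): {shortfalls}")
    return frames.loc[selected].sort_index()


def _majority_labels(labels: pd.DataFrame) -> pd.Series:
    """Participant-level stratification key: per-dimension majority label."""

    def key(grp: pd.DataFrame) -> str:
        parts = []
        for dim in DIMENSIONS:
            sub = grp[grp["dimension"] == dim]["label"]
            parts.append(str(int(round(sub.mean()))) if len(sub) else "0")
        return "".join(parts)

    return labels.groupby("participant")[labels.columns.to_list()].apply(key)


def partition_participants(
    groups: pd.Series,
    labels: pd.DataFrame,
    config: SelectionConfig,
    seed: int = 0,
) -> SplitSpec:
    """Build the fixed test set and the stratified 8:2 train/val split.

    ``groups`` maps participant id -> "High"/"Low". The test set samples
    ``test_high`` participants from High and ``test_low`` from Low (seeded);
    it is meant to be held fixed across all training-group configurations.
    The remaining participants are split train:val = ``train_val_ratio`` :
    rest within strata defined by participant-majority binary labels, so the
    label distribution stays comparable across the two partitions.
    """
    rng = np.random.default_rng([11, seed])
    groups = pd.Series(groups)
    test: list[str] = []
    test_by_group: dict[str, list[str]] = {}
    for gname, n_test in (("High", config.test_high), ("Low", config.test_low)):
        members = sorted(groups.index[groups == gname])
        if len(members) < n_test + 1:
            raise PartitionError(
                f"group {gname} has {len(members)} participants; needs > {n_test}"
            )
        picked = sorted(rng.choice(members, size=n_test, replace=False).tolist())
        test_by_group[gname] = picked
        test.extend(picked)

    remaining = sorted(set(groups.index) - set(test))
    strat = _majority_labels(labels[labels["participant"].isin(remaining)])
    train: list[str] = []
    val: list[str] = []
    for _, members in strat.groupby(strat):
        ids = sorted(members.index)
        perm = rng.permutation(len(ids))
        n_val = int(round((1.0 - config.train_val_ratio) * len(ids)))
        val.extend(ids[i] for i in perm[:n_val])
        train.extend(ids[i] for i in perm[n_val:])
    if not val and train:  # tiny cohorts: keep validation nonempty
        val.append(train.pop())
    spec = SplitSpec(
        train=sorted(train), val=sorted(val), test=sorted(test), test_by_group=test_by_group
    )
    spec.validate(groups.index)
    return spec


def build_ambiguity_subsets(
    test_frames: pd.DataFrame,
    labels: pd.DataFrame,
    dimension: str,
    config: SelectionConfig,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[tuple]]:
    """Draw matched unambiguous/ambiguous test strata from the raw frame pool.

    Within each (participant, video): the unambiguous pool holds
    sign-congruent frames with |estimate| at or above the cell's upper
    quantile; the ambiguous pool holds sign-incongruent frames or frames
    below the lower quantile. ``frames_per_video_subset`` frames (default 6)
    are sampled uniformly (seeded) from each pool; cells with fewer
    qualifying frames contribute all they have and are flagged.

    Returns (unambiguous frames, ambiguous frames, flagged cells).
    """
    if "valid" in test_frames.columns:
        test_frames = test_frames[test_frames["valid"]]
    merged = _with_direction(test_frames, labels, dimension)
    est = merged[f"{dimension}_est"].to_numpy()
    merged = merged.assign(
        _mag=np.abs(est), _congruent=np.sign(est) == merged["direction"].to_numpy()
    )

    rng = np.random.default_rng([13, seed])
    n_sub = config.frames_per_video_subset
    unamb_idx: list[int] = []
    amb_idx: list[int] = []
    flagged: list[tuple] = []
    for key, cell in merged.groupby(["participant", "video"], sort=True):
        t_hi = cell["_mag"].quantile(config.unambiguous_upper_quantile)
        t_lo = cell["_mag"].quantile(config.ambiguous_lower_quantile)
        pool_u = cell.index[cell["_congruent"] & (cell["_mag"] >= t_hi)].to_list()
        pool_a = cell.index[(~cell["_congruent"]) | (cell["_mag"] < t_lo)].to_list()
        for tag, pool, out in (("unambiguous", pool_u, unamb_idx), ("ambiguous", pool_a, amb_idx)):
            if len(pool) < n_sub:
                flagged.append((key, tag, len(pool)))
                out.extend(pool)
            else:
                out.extend(sorted(rng.choice(pool, size=n_sub, replace=False).tolist()))
    if flagged:
        warnings.warn(f"ambiguity cells with fewer than {n_sub} qualifying frames: {flagged}")
    return test_frames.loc[unamb_idx], test_frames.loc[amb_idx], flagged
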