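import numpy as np
import pandas as pd
import pytest

from eistrat.config import SelectionConfig
from eistrat.selection import (
    PartitionError,
    build_ambiguity_subsets,
    congruence_filter,
    frame_ids,
    partition_participants,
    select_top_frames,
)


def _labels(rows):
    return pd.DataFrame(rows, columns=["participant", "video", "dimension", "label"])


def _frames(rows):
    return pd.DataFrame(
        rows, columns=["participant", "video", "frame", "arousal_est", "valence_est"]
    )


class TestCongruenceFilter:
    labels = _labels(
        [("P1", "V1", "arousal", 1), ("P1", "V1", "valence", 0)]
    )

    def test_sign_match_retained_mismatch_excluded(self):
        frames = _frames(
            [
                ("P1", "V1", 0, +0.5, -0.2),  # arousal congruent
                ("P1", "V1", 1, -0.3, -0.2),  # arousal incongruent
                ("P1", "V1", 2, 0.0, -0.2),  # zero: no sign, excluded
            ]
        )
        kept = congruence_filter(frames, self.labels, "arousal")
        assert kept["frame"].to_list() == [0]

    def test_low_label_requires_negative_sign(self):
        frames = _frames([("P1", "V1", 0, 0.1, -0.4), ("P1", "V1", 1, 0.1, +0.4)])
        kept = congruence_filter(frames, self.labels, "valence")
        assert kept["frame"].to_list() == [0]

    def test_invalid_frames_dropped_first(self):
        frames = _frames([("P1", "V1", 0, +0.5, -0.2)]).assign(valid=[False])
        assert congruence_filter(frames, self.labels, "arousal").empty


class TestTopFrameSelection:
    def test_abundant_supply_yields_2k_per_video(self, default_state):
        cfg = default_state["config"].selection
        frames = default_state["frames"]
        labels = default_state["labels"]
        one = frames[frames["participant"] == frames["participant"].iloc[0]]
        sel = select_top_frames(one, labels, cfg)
        per_video = sel.groupby("video").size()
        assert (per_video == 2 * cfg.k_per_dimension).all()
        assert len(sel) == 4 * 2 * cfg.k_per_dimension == 800

    def test_shortfall_takes_all_available_with_warning(self):
        rng = np.random.default_rng(0)
        labels = _labels([("P1", "V1", "arousal", 1), ("P1", "V1", "valence", 1)])
        frames = _frames(
            [("P1", "V1", i, +rng.uniform(0.1, 1), -rng.uniform(0.1, 1)) for i in range(50)]
        )  # all valence-incongruent: only 50 arousal-congruent frames exist
        with pytest.warns(UserWarning, match="shortfall"):
            sel = select_top_frames(frames, labels, SelectionConfig(k_per_dimension=100))
        assert len(sel) == 50

    def test_magnitude_ties_break_toward_lower_frame_index(self):
        labels = _labels([("P1", "V1", "arousal", 1), ("P1", "V1", "valence", 1)])
        frames = _frames(
            [
                ("P1", "V1", 3, 0.5, 0.9),
                ("P1", "V1", 1, 0.5, 0.8),
                ("P1", "V1", 2, 0.5, 0.7),
            ]
        )
        sel = select_top_frames(frames, labels, SelectionConfig(k_per_dimension=1))
        # top-1 arousal is the tie at |0.5| -> frame 1 wins; top-1 valence is frame 3
        assert set(sel["frame"]) == {1, 3}

    def test_top_k_by_magnitude_always_included(self, default_state):
        """The k largest congruent frames per dimension are always selected."""
        cfg = default_state["config"].selection
        frames = default_state["frames"]
        labels = default_state["labels"]
        pid = frames["participant"].iloc[0]
        one = frames[(frames["participant"] == pid) & (frames["video"] == "V1")]
        sel = select_top_frames(one, labels, cfg)
        for dim in ("arousal", "valence"):
            cong = congruence_filter(one, labels, dim)
            top_k = cong.reindex(
                cong[f"{dim}_est"].abs().sort_values(ascending=False).index
            ).head(cfg.k_per_dimension)
            assert top_k.index.isin(sel.index).all()


class TestPartitioning:
    def _cohort(self, n_high=23, n_low=21):
        ids = [f"P{i:02d}" for i in range(n_high + n_low)]
        groups = pd.Series(["High"] * n_high + ["Low"] * n_low, index=ids)
        rng = np.random.default_rng(5)
        labels = pd.DataFrame(
            [
                (p, "V1", dim, int(rng.random() < 0.5))
                for p in ids
                for dim in ("arousal", "valence")
            ],
            columns=["participant", "video", "dimension", "label"],
        )
        return groups, labels

    def test_fixed_test_set_is_two_plus_two(self):
        groups, labels = self._cohort()
        spec = partition_participants(groups, labels, SelectionConfig(), seed=0)
        assert len(spec.test) == 4
        assert len(spec.test_by_group["High"]) == 2 and len(spec.test_by_group["Low"]) == 2
        assert groups[spec.test_by_group["High"]].eq("High").all()

    def test_partition_deterministic_and_disjoint(self):
        groups, labels = self._cohort()
        a = partition_participants(groups, labels, SelectionConfig(), seed=9)
        b = partition_participants(groups, labels, SelectionConfig(), seed=9)
        assert (a.train, a.val, a.test) == (b.train, b.val, b.test)
        assert not (set(a.train) & set(a.val) | set(a.train) & set(a.test) | set(a.val) & set(a.test))
        assert set(a.train) | set(a.val) | set(a.test) == set(groups.index)

    def test_split_ratio_approximately_eight_to_two(self):
        groups, labels = self._cohort()
        spec = partition_participants(groups, labels, SelectionConfig(), seed=1)
        n = len(spec.train) + len(spec.val)
        assert abs(len(spec.train) / n - 0.8) < 0.1

    def test_insufficient_group_raises(self):
        groups, labels = self._cohort(n_high=2, n_low=21)
        with pytest.raises(PartitionError):
            partition_participants(groups, labels, SelectionConfig(), seed=0)


class TestAmbiguitySubsets:
    def test_study_shape_96_frames_per_subset(self, default_state):
        cfg = default_state["config"]
        frames = default_state["frames"]
        test_pool = frames[frames["participant"].isin(default_state["split"].test)]
        unamb, amb, flagged = build_ambiguity_subsets(
            test_pool, default_state["labels"], "arousal", cfg.selection, seed=0
        )
        assert not flagged
        assert len(unamb) == len(amb) == 4 * 4 * 6 == 96
        assert (unamb.groupby("participant").size() == 24).all()
        assert (amb.groupby("participant").size() == 24).all()
        assert not set(frame_ids(unamb)) & set(frame_ids(amb))

    def test_unambiguous_frames_are_congruent_high_magnitude(self, default_state):
        cfg = default_state["config"]
        frames = default_state["frames"]
        labels = default_state["labels"]
        test_pool = frames[frames["participant"].isin(default_state["split"].test)]
        unamb, amb, _ = build_ambiguity_subsets(test_pool, labels, "valence", cfg.selection, seed=0)
        lab = labels[labels["dimension"] == "valence"].set_index(["participant", "video"])["label"]
        for df, expect_congruent in ((unamb, True), (amb, None)):
            direction = np.where(
                lab.loc[list(zip(df["participant"], df["video"]))].to_numpy() == 1, 1, -1
            )
            congruent = np.sign(df["valence_est"].to_numpy()) == direction
            if expect_congruent:
                assert congruent.all()
        assert unamb["valence_est"].abs().mean() > amb["valence_est"].abs().mean()

    def test_sparse_cells_flagged(self):
        labels = _labels([("P1", "V1", "arousal", 1), ("P1", "V1", "valence", 1)])
        frames = _frames([("P1", "V1", i, 0.5 + 0.01 * i, 0.5) for i in range(8)])
        with pytest.warns(UserWarning, match="fewer than"):
            unamb, amb, flagged = build_ambiguity_subsets(
                frames, labels, "arousal", SelectionConfig(), seed=0
            )
        assert flagged and len(amb) < 6


def test_no_test_frames_from_training_participants(default_state):
    """Leakage check: every test-subset frame belongs to a test participant."""
    split = default_state["split"]
    train_val = set(split.train) | set(split.val)
    for dim_map in (split.baseline_frames, split.unambiguous_frames, split.ambiguous_frames):
        for ids in dim_map.values():
            owners = {fid.split(":")[0] for fid in ids}
            assert owners <= set(split.test)
            assert not owners & train_val
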