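"""Validated configuration models for the simulation/analysis pipeline.

All knobs that shape the study design live here: cohort size and EI
distribution, the EI→congruence consistency map, frame-magnitude shapes, HRV
effect injection, frame-selection counts, classifier training schedule and
threshold grid, and the repetition count of the comparison framework.
Defaults mirror the study protocol (44 participants, 4 quadrant videos,
k = 100 frames per dimension, 2+2 fixed test participants, 8:2 split,
λ = 0.4, threshold grid 0.2–0.8, 5 repetitions).
"""

from __future__ import annotations

import math
from typing import Literal

from pydantic import BaseModel, Field, model_validator


class ConsistencyMap(BaseModel):
    """Monotone logistic map from EI score (0–1200) to congruence probability.

    p(EI) = p_lo + (p_hi − p_lo) · sigmoid((EI − midpoint) / scale)

    Nondecreasing in EI by construction (scale > 0, p_hi ≥ p_lo), so
    higher-EI participants produce frames whose estimated affect sign agrees
    with their subjective label more often.
    """

    p_lo: float = Field(0.55, gt=0.0, lt=1.0)
    p_hi: float = Field(0.95, gt=0.0, lt=1.0)
    midpoint: float = Field(700.0, ge=0.0, le=1200.0)
    scale: float = Field(150.0, gt=0.0)

    @model_validator(mode="after")
    def _ordered(self) -> "ConsistencyMap":
        if self.p_hi < self.p_lo:
            raise ValueError("p_hi must be >= p_lo (map must be nondecreasing)")
        return self

    def __call__(self, ei: float) -> float:
        z = (float(ei) - self.midpoint) / self.scale
        return self.p_lo + (self.p_hi - self.p_lo) / (1.0 + math.exp(-z))


class BetaShape(BaseModel):
    """Beta(a, b) shape for |estimate| magnitudes in (0, 1)."""

    a: float = Field(gt=0.0)
    b: float = Field(gt=0.0)


class MagnitudeParams(BaseModel):
    """Magnitude distributions for congruent vs incongruent frames.

    Congruent frames are stochastically larger in |estimate| (defaults
    Beta(4,2) vs Beta(2,4)), so congruence-based magnitude ranking is
    meaningful and low-|estimate| frames are intrinsically ambiguous.
    """

    congruent: BetaShape = BetaShape(a=4.0, b=2.0)
    incongruent: BetaShape = BetaShape(a=2.0, b=4.0)


class SimConfig(BaseModel):
    """Synthetic-cohort generator configuration."""

    n_participants: int = Field(44, ge=1)
    n_videos_per_participant: int = Field(4, ge=1)
    frames_per_video: int = Field(300, ge=1)
    ei_mean: float = 825.0
    ei_sd: float = Field(150.0, ge=0.0)
    consistency_map: ConsistencyMap = ConsistencyMap()
    neutral_rating_prob: float = Field(0.15, ge=0.0, le=1.0)
    rating_sd: float = Field(1.2, gt=0.0)
    magnitude_params: MagnitudeParams = MagnitudeParams()

    # HRV table: one row per participant × emotion condition; the "true"
    # grouping cutoff is independent of the cutoff scanner under test.
    n_hrv_vars: int = Field(8, ge=0)
    hrv_effect: float | list[float] = 0.0
    hrv_true_cutoff: float = Field(830.0, ge=0.0, le=1200.0)
    hrv_group_effect: float = 0.3
    hrv_emotion_effect: float = 0.3
    hrv_noise_sd: float = Field(1.0, ge=0.0)

    # Classifier features: per affect dimension a few informative coordinates
    # proportional to the frame's continuous estimate, plus pure noise dims.
    n_informative_per_dim: int = Field(3, ge=1)
    n_noise_features: int = Field(8, ge=0)
    feature_noise_sd: float = Field(0.25, ge=0.0)

    seed: int = 0

    def hrv_effects(self) -> list[float]:
        """Per-variable interaction effect sizes, broadcast if scalar."""
        if isinstance(self.hrv_effect, list):
            if len(self.hrv_effect) != self.n_hrv_vars:
                raise ValueError(
                    f"hrv_effect list length {len(self.hrv_effect)} != n_hrv_vars {self.n_hrv_vars}"
                )
            return [float(e) for e in self.hrv_effect]
        return [float(self.hrv_effect)] * self.n_hrv_vars


class SelectionConfig(BaseModel):
    """Frame-selection and partitioning configuration."""

    k_per_dimension: int = Field(100, ge=1)
    frames_per_video_subset: int = Field(6, ge=1)
    test_high: int = Field(2, ge=1)
    test_low: int = Field(2, ge=1)
    train_val_ratio: float = Field(0.8, gt=0.0, lt=1.0)
    # |estimate| quantile cuts within (participant, video, dimension):
    # "larger" = at or above the upper cut, "smaller" = below the lower cut.
    unambiguous_upper_quantile: float = Field(2.0 / 3.0, gt=0.0, lt=1.0)
    ambiguous_lower_quantile: float = Field(1.0 / 3.0, gt=0.0, lt=1.0)

    @model_validator(mode="after")
    def _ordered(self) -> "SelectionConfig":
        if self.ambiguous_lower_quantile > self.unambiguous_upper_quantile:
            raise ValueError("ambiguous_lower_quantile must be <= unambiguous_upper_quantile")
        return self


class Stage(BaseModel):
    """One training stage: which components train, for how long, how fast."""

    scope: Literal["heads", "all"]
    epochs: int = Field(ge=1)
    lr: float = Field(gt=0.0)


class TrainingConfig(BaseModel):
    """Joint-loss classifier training configuration.

    Stage 1 freezes the encoder and trains only the heads; stage 2 fine-tunes
    everything — mirroring staged fine-tuning of a pretrained backbone at
    desk scale.
    """

    lambda_reg: float = Field(0.4, ge=0.0)
    hidden_sizes: tuple[int, int] = (32, 16)
    stage_schedule: list[Stage] = [
        Stage(scope="heads", epochs=4, lr=3e-4),
        Stage(scope="all", epochs=6, lr=1e-4),
    ]
    batch_size: int = Field(32, ge=1)
    weight_decay: float = Field(1e-2, ge=0.0)
    clip_norm: float = Field(1.0, gt=0.0)
    warmup_epochs: int = Field(3, ge=0)  # linear warm-up per stage, then cosine
    threshold_lo: float = Field(0.2, gt=0.0, lt=1.0)
    threshold_hi: float = Field(0.8, gt=0.0, lt=1.0)
    threshold_step: float = Field(0.01, gt=0.0)
    feature_jitter_sd: float = Field(0.0, ge=0.0)  # optional train-time jitter

    @model_validator(mode="after")
    def _grid(self) -> "TrainingConfig":
        if self.threshold_hi < self.threshold_lo:
            raise ValueError("threshold_hi must be >= threshold_lo")
        return self


class CutoffConfig(BaseModel):
    """EI cutoff scan configuration."""

    alpha: float = Field(0.05, gt=0.0, lt=1.0)
    grid_step: float = Field(10.0, gt=0.0)
    percentile_range: tuple[float, float] = (10.0, 90.0)
    max_imbalance_frac: float = Field(0.2, gt=0.0, le=1.0)


class PipelineConfig(BaseModel):
    """End-to-end run configuration (one JSON document)."""

    sim: SimConfig = SimConfig()
    selection: SelectionConfig = SelectionConfig()
    training: TrainingConfig = TrainingConfig()
    cutoff: CutoffConfig = CutoffConfig()
    repetitions: int = Field(5, ge=1)
    transfer: bool = False
    alpha: float = Field(0.05, gt=0.0, lt=1.0)
    seed: int = 0
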