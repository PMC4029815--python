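"""Decision-value to ring-distortion feedback mapping.

Feedback is a ring whose distortion encodes the decoder's confidence:
level 1 (most distorted) signals misclassification; levels 2..20 encode
increasing signed distance of a correctly classified volume from the
hyperplane, saturating to a perfectly smooth ring at ``d_max``.  Control
subjects see a seeded uniform-random level stream instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .design import Condition

N_LEVELS = 20
#: level offset for chance: the mid-scale level used by the learning model
MID_LEVEL = (1 + N_LEVELS) / 2.0  # 10.5


@dataclass(frozen=True)
class FeedbackConfig:
    d_max: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ValueError("d_max must be > 0")


@dataclass(frozen=True)
class FeedbackFrame:
    volume_index: int
    decision_value: float
    target_condition: Condition
    correct: bool
    level: int
    contingent: bool

    def __post_init__(self) -> None:
        if not 1 <= self.level <= N_LEVELS:
            raise ValueError(f"level {self.level} outside [1, {N_LEVELS}]")
        if self.contingent and (self.level == 1) != (not self.correct):
            raise ValueError("contingent frames: level 1 iff misclassified")


def toward_target_distance(d: float, target_condition: Condition) -> float:
    """Signed distance toward the target class (+ = correct side)."""
    if target_condition is Condition.TENDERNESS:
        return d
    if target_condition is Condition.PRIDE:
        return -d
    raise ValueError("target must be an emotional condition")


def map_level(
    d: float,
    target_condition: Condition,
    cfg: FeedbackConfig = FeedbackConfig(),
    volume_index: int = -1,
) -> FeedbackFrame:
    """Quantize a decision value into the 20-level ring code.

    s <= 0 (wrong side of the hyperplane, or exactly on it) gives level 1;
    otherwise level = 1 + ceil(min(s, d_max)/d_max * 19), a monotone
    non-decreasing step function of s with exactly 20 attainable values.
    """
    if not math.isfinite(d):
        raise ValueError("decision value must be finite")
    s = toward_target_distance(d, target_condition)
    if s <= 0:
        level = 1
        correct = False
    else:
        level = 1 + min(N_LEVELS - 1, math.ceil(min(s, cfg.d_max) / cfg.d_max * (N_LEVELS - 1)))
        correct = True
    return FeedbackFrame(
        volume_index=volume_index,
        decision_value=float(d),
        target_condition=target_condition,
        correct=correct,
        level=level,
        contingent=True,
    )


def random_stream(
    n: int, cfg: FeedbackConfig = FeedbackConfig()
) -> list[FeedbackFrame]:
    """Non-contingent control stream: i.i.d. uniform levels on {1..20}."""
    rng = np.random.default_rng(cfg.seed)
    levels = rng.integers(1, N_LEVELS + 1, size=n)
    return [
        FeedbackFrame(
            volume_index=i,
            decision_value=float("nan"),
            target_condition=Condition.NEUTRAL,
            correct=False,
            level=int(lv),
            contingent=False,
        )
        for i, lv in enumerate(levels)
    ]


def ring_coordinates(level: int, n_points: int = 128, seed: int = 0) -> np.ndarray:
    """Closed 2D polyline of the feedback ring at a distortion level.

    Unit circle with seeded radial perturbation of amplitude proportional
    to (20 - level)/19; level 20 is a perfect circle.  Returns an
    (n_points + 1, 2) array whose last point repeats the first.
    """
    if not 1 <= level <= N_LEVELS:
        raise ValueError("level outside [1, 20]")
    rng = np.random.default_rng(seed)
    theta = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    amplitude = 0.3 * (N_LEVELS - level) / (N_LEVELS - 1)
    # smooth perturbation: a few random low-order harmonics
    radii = np.ones(n_points)
    for k in range(2, 7):
        phase = rng.uniform(0, 2 * np.pi)
        radii += amplitude * rng.uniform(0.2, 1.0) / 2.5 * np.cos(k * theta + phase)
    pts = np.column_stack([radii * np.cos(theta), radii * np.sin(theta)])
    return np.vstack([pts, pts[:1]])
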