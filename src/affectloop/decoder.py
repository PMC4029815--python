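"""Two-class linear max-margin decoder over masked voxel features.

The decoder is a soft-margin linear SVM: class +1 = tenderness, -1 =
pride.  The decision value x.w + b is the signed projection onto the
separating hyperplane; its absolute-coefficient ranking yields the
discriminant-voxel maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.svm import SVC

from .design import Condition
from .preproc import FeatureVector


class TrainingError(ValueError):
    pass


class FeatureError(ValueError):
    pass


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass(frozen=True)
class Decoder:
    """Trained hyperplane (w, b); positive decision value = tenderness."""

    w: np.ndarray
    b: float
    c_param: float = 1.0
    trained_on: tuple[int, ...] = ()
    feature_order: str = "row-major-xyz"

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.w)) and np.isfinite(self.b)):
            raise TrainingError("non-finite decoder parameters")

    @property
    def n_features(self) -> int:
        return self.w.size

    def decision_value(self, x: FeatureVector | np.ndarray) -> float:
        """Signed distance proxy x.w + b (positive => tenderness side)."""
        values = x.values if isinstance(x, FeatureVector) else np.asarray(x, float)
        if values.size != self.w.size:
            raise FeatureError(
                f"feature length {values.size} != decoder length {self.w.size}"
            )
        return float(values @ self.w + self.b)

    def classify(self, x: FeatureVector | np.ndarray) -> Condition:
        """Tenderness iff decision value > 0; an exact zero is called pride
        so tenderness-classification claims stay conservative."""
        return (
            Condition.TENDERNESS
            if self.decision_value(x) > 0
            else Condition.PRIDE
        )


def train(
    features: Sequence[FeatureVector] | np.ndarray,
    labels: Sequence[int],
    c_param: float = 1.0,
    trained_on: tuple[int, ...] = (),
    tol: float = 1e-3,
) -> Decoder:
    """Fit the soft-margin linear SVM.

    ``labels`` are +1 (tenderness) / -1 (pride).  With separable data and
    large ``c_param`` the solution approaches the hard-margin optimum.
    """
    if len(features) and isinstance(features[0], FeatureVector):
        X = np.asarray([f.values for f in features], dtype=float)
    else:
        X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise TrainingError("feature matrix / label length mismatch")
    if len(np.unique(y)) < 2:
        raise TrainingError("training needs both classes")
    svc = SVC(kernel="linear", C=c_param, tol=tol)
    svc.fit(X, y)
    w = svc.coef_.ravel().astype(float)
    b = float(svc.intercept_[0])
    # sklearn orients the hyperplane toward the larger class label; with
    # labels +1/-1 positive decision values already mean class +1.
    return Decoder(w=w, b=b, c_param=c_param, trained_on=trained_on)


CONDITION_SIGN = {Condition.TENDERNESS: +1, Condition.PRIDE: -1}


def train_from_run(
    features: Sequence[FeatureVector],
    c_param: float = 1.0,
    trained_on: tuple[int, ...] = (),
) -> Decoder:
    """Train from usable-volume feature vectors, labels from conditions."""
    emo = [f for f in features if f.condition in CONDITION_SIGN]
    y = [CONDITION_SIGN[f.condition] for f in emo]
    return train(emo, y, c_param=c_param, trained_on=trained_on)


def retrain_schedule(
    runs: Mapping[int, Sequence[FeatureVector]], c_param: float = 1.0
) -> dict[int, Decoder]:
    """Per-session decoders: session k uses a decoder trained on run k-1.

    ``runs`` maps run index (1-based session order) to that run's usable
    feature vectors.  Session 1 is training-only and gets no decoder.
    """
    if not runs:
        raise TrainingError("need at least one completed run")
    schedule: dict[int, Decoder] = {}
    for run_id in sorted(runs):
        schedule[run_id + 1] = train_from_run(
            runs[run_id], c_param=c_param, trained_on=(run_id,)
        )
    return schedule


@dataclass(frozen=True)
class DiscriminantMap:
    """|w| per feature voxel and the top-fraction discriminant mask."""

    abs_weight: np.ndarray
    top_fraction_mask: np.ndarray
    fraction: float


def discriminant_map(decoder: Decoder, fraction: float = 0.02) -> DiscriminantMap:
    """Flag the top ``fraction`` of voxels by |w|.

    The count is round-half-away-from-zero of fraction * n; ties in |w|
    are broken by voxel order (earlier voxel wins), so the map is
    deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    aw = np.abs(decoder.w)
    n_top = min(aw.size, max(_round_half_away(fraction * aw.size), 0))
    # stable sort on (-|w|, index): ties resolved by voxel order
    order = np.lexsort((np.arange(aw.size), -aw))
    mask = np.zeros(aw.size, dtype=bool)
    mask[order[:n_top]] = True
    return DiscriminantMap(aw, mask, fraction)


def consistency_map(maps: Sequence[DiscriminantMap]) -> np.ndarray:
    """Per-voxel fraction of subjects whose discriminant mask includes it."""
    if not maps:
        raise ValueError("no discriminant maps given")
    stack = np.asarray([m.top_fraction_mask for m in maps], dtype=float)
    if stack.ndim != 2:
        raise ValueError("maps do not share a feature grid")
    return stack.mean(axis=0)


def consistency_threshold(fractions: np.ndarray, level: float) -> np.ndarray:
    """Voxels present in at least ``level`` of the subjects (0.40 / 0.66)."""
    return np.asarray(fractions) >= level


def save_decoder(decoder: Decoder, path: str | Path) -> None:
    path = Path(path)
    payload = {
        "b": decoder.b,
        "c_param": decoder.c_param,
        "trained_on": list(decoder.trained_on),
        "feature_order": decoder.feature_order,
        "w": decoder.w.tolist(),
    }
    path.write_text(json.dumps(payload))


def load_decoder(path: str | Path) -> Decoder:
    payload = json.loads(Path(path).read_text())
    return Decoder(
        w=np.asarray(payload["w"], dtype=float),
        b=float(payload["b"]),
        c_param=float(payload["c_param"]),
        trained_on=tuple(payload["trained_on"]),
        feature_order=payload["feature_order"],
    )
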