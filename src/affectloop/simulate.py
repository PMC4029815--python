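"""Closed-loop synthetic fMRI subjects.

Generates block-design BOLD runs whose statistical structure matches
what the real-time decoder assumes: condition-specific spatial patterns
inside a feature mask, hemodynamically convolved block responses, slow
linear drift, and AR(1) temporal noise.  A latent learning rule couples
the displayed feedback back to the tenderness pattern amplitude, so
neurofeedback (NFB) subjects can improve across sessions while control
(CTR) subjects, whose rings are random, cannot.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import decoder as dec
from . import feedback as fb
from .design import BlockDesign, Condition, label_volumes, make_default_design
from .glm import condition_boxcars, hrf_kernel
from .preproc import PreprocConfig, VolumeStream
from .stats import Group, SubjectOutcome, pct_tenderness


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class AcquisitionGrid:
    """Desk-scale voxel lattice standing in for a full EPI matrix."""

    dims: tuple[int, int, int] = (24, 24, 12)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(
            self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm)
        )
        if len(self.dims) != 3 or any(d < 4 for d in self.dims):
            raise ConfigError("grid needs three dims, all >= 4")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ConfigError("voxel sizes must be positive")

    @property
    def n_voxels(self) -> int:
        d = self.dims
        return d[0] * d[1] * d[2]


@dataclass(frozen=True)
class PatternAtlas:
    """Spatial layout of the synthetic brain.

    Two disjoint ellipsoidal activation patterns (tenderness, pride)
    inside a larger feature mask, plus a small a-priori ROI overlapping
    the tenderness pattern (stand-in for the septohypothalamic mask used
    in small-volume correction).
    """

    grid: AcquisitionGrid
    tenderness_pattern: np.ndarray
    pride_pattern: np.ndarray
    feature_mask: np.ndarray
    svc_roi: np.ndarray

    def __post_init__(self) -> None:
        fm = self.feature_mask
        if (self.tenderness_pattern[~fm] != 0).any() or (
            self.pride_pattern[~fm] != 0
        ).any():
            raise ConfigError("patterns must vanish outside the feature mask")
        if not np.all(fm[self.svc_roi]):
            raise ConfigError("svc_roi must lie inside the feature mask")


def _ellipsoid(dims, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, d) for d in dims)]
    acc = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return acc <= 1.0


def make_atlas(grid: AcquisitionGrid = AcquisitionGrid(), seed: int = 0) -> PatternAtlas:
    """Place the feature mask, the two patterns, and the SVC ROI.

    Pattern voxel magnitudes are drawn uniformly in [0.5, 1] (seeded), so
    the two patterns are linearly independent and spatially structured.
    """
    nx, ny, nz = grid.dims
    cx, cy, cz = nx / 2 - 0.5, ny / 2 - 0.5, nz / 2 - 0.5
    feature_mask = _ellipsoid(grid.dims, (cx, cy, cz), (nx * 0.42, ny * 0.42, nz * 0.45))
    tend_region = _ellipsoid(
        grid.dims, (cx - nx * 0.2, cy, cz), (nx * 0.12, ny * 0.16, nz * 0.25)
    )
    pride_region = _ellipsoid(
        grid.dims, (cx + nx * 0.2, cy, cz), (nx * 0.12, ny * 0.16, nz * 0.25)
    )
    tend_region &= feature_mask
    pride_region &= feature_mask
    if tend_region.sum() < 8 or pride_region.sum() < 8 or (tend_region & pride_region).any():
        raise ConfigError("grid too small to place disjoint pattern regions")
    svc_roi = _ellipsoid(
        grid.dims, (cx - nx * 0.2, cy, cz), (nx * 0.08, ny * 0.1, nz * 0.18)
    ) & tend_region
    if not svc_roi.any():
        raise ConfigError("grid too small for an SVC ROI")

    rng = np.random.default_rng(seed)
    tenderness = np.zeros(grid.dims)
    pride = np.zeros(grid.dims)
    tenderness[tend_region] = rng.uniform(0.5, 1.0, tend_region.sum())
    pride[pride_region] = rng.uniform(0.5, 1.0, pride_region.sum())
    return PatternAtlas(grid, tenderness, pride, feature_mask, svc_roi)


@dataclass(frozen=True)
class SubjectState:
    """Latent generative parameters of one synthetic subject.

    amp_* are pattern amplitudes in baseline-signal units; learning_rate
    scales the between-run amplitude update from feedback; noise_sd and
    ar_coeff set the marginal sd and lag-1 autocorrelation of the voxel
    noise; drift_slope is signal units per volume.
    """

    amp_tenderness: float = 0.7
    amp_pride: float = 0.7
    learning_rate: float = 0.0
    noise_sd: float = 10.0
    ar_coeff: float = 0.3
    drift_slope: float = 0.01
    group: Group = Group.NFB
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if not 0.0 <= self.ar_coeff < 1.0:
            raise ConfigError("ar_coeff must be in [0, 1)")
        if self.learning_rate < 0:
            raise ConfigError("learning_rate must be >= 0")


@dataclass(frozen=True)
class VolumeSeries:
    """One run's 4D data, time on the first axis."""

    grid: AcquisitionGrid
    data: np.ndarray  # (n_volumes, x, y, z)
    run_id: int
    design: BlockDesign

    def __post_init__(self) -> None:
        if self.data.shape[0] != self.design.n_volumes:
            raise ConfigError("time length != design volumes")
        if not np.all(np.isfinite(self.data)):
            raise ConfigError("non-finite voxel values")


BASELINE_SIGNAL = 100.0


def _ar1_noise(rng: np.random.Generator, shape_t_v: tuple[int, int], sd: float, phi: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal sd ``sd`` and lag-1 corr phi."""
    n_t, n_v = shape_t_v
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    out = np.empty((n_t, n_v))
    out[0] = rng.normal(0.0, sd, n_v)
    for t in range(1, n_t):
        out[t] = phi * out[t - 1] + rng.normal(0.0, innov_sd, n_v)
    return out


def simulate_run(
    state: SubjectState,
    atlas: PatternAtlas,
    design: BlockDesign,
    feedback_stream=None,
    run_id: int = 0,
) -> VolumeSeries:
    """Generate one run.

    data = baseline + sum_c amp_c * pattern_c * (HRF * boxcar_c)
           + drift_slope * t + AR(1) noise.
    Neutral blocks carry baseline + drift + noise only.  The optional
    ``feedback_stream`` (displayed ring levels) does not alter the
    within-run signal -- learning acts between runs -- but its length is
    validated so closed-loop bookkeeping errors surface early.
    """
    if feedback_stream is not None and len(feedback_stream) != design.n_volumes:
        raise ConfigError("feedback stream length != design volumes")
    n = design.n_volumes
    h = hrf_kernel(design.tr_seconds)
    box = condition_boxcars(design)
    resp = {
        c: np.convolve(box[c], h)[:n]
        for c in (Condition.TENDERNESS, Condition.PRIDE)
    }
    t_axis = np.arange(n)
    rng = np.random.default_rng(state.rng_seed + run_id)

    data = np.full((n,) + atlas.grid.dims, BASELINE_SIGNAL)
    data += (state.drift_slope * t_axis)[:, None, None, None]
    data += np.einsum(
        "t,xyz->txyz", state.amp_tenderness * resp[Condition.TENDERNESS], atlas.tenderness_pattern
    )
    data += np.einsum(
        "t,xyz->txyz", state.amp_pride * resp[Condition.PRIDE], atlas.pride_pattern
    )
    if state.noise_sd > 0:
        noise = _ar1_noise(rng, (n, atlas.grid.n_voxels), state.noise_sd, state.ar_coeff)
        data += noise.reshape((n,) + atlas.grid.dims)
    return VolumeSeries(atlas.grid, data, run_id, design)


def update_state(
    state: SubjectState, mean_feedback_level: float, contingent: bool
) -> SubjectState:
    """Between-run learning rule.

    Contingent (NFB) subjects shift their tenderness amplitude by
    learning_rate * (mean level - 10.5)/9.5, floored at zero; random
    (CTR) feedback leaves the state unchanged.
    """
    if not 1.0 <= mean_feedback_level <= 20.0:
        raise ConfigError("mean feedback level outside [1, 20]")
    if not contingent:
        return state
    delta = state.learning_rate * (mean_feedback_level - fb.MID_LEVEL) / 9.5
    return replace(state, amp_tenderness=max(0.0, state.amp_tenderness + delta))


@dataclass
class SessionLog:
    """One classification session's decoding record for a subject."""

    run_id: int
    frames: pd.DataFrame  # volume_index, decision_value, level, correct, contingent
    pct_tenderness: float
    tenderness_counts: tuple[int, int]  # (classified tenderness, usable)
    mean_displayed_level: float


@dataclass
class SubjectRecord:
    subject_id: str
    group: Group
    sessions: list[SessionLog]
    final_state: SubjectState
    outcome: SubjectOutcome
    series: list[VolumeSeries] | None = None


DEFAULT_NFB_LEARNING_RATE = 3.0

#: Ring-display saturation distance used by the simulator's feedback loop.
#: Out-of-sample decision values are much smaller than the training margin
#: (heavy shrinkage with ~2e3 voxel features and 160 training volumes), so
#: the display is calibrated to the decision-value scale the decoder
#: actually emits on unseen volumes; saturating at the margin itself would
#: confine the rings to the lowest levels and starve the learning signal.
DISPLAY_D_MAX = 0.3


def simulate_subject(
    base_state: SubjectState,
    atlas: PatternAtlas,
    n_runs: int = 4,
    subject_id: str = "sub-00",
    start_condition: Condition = Condition.TENDERNESS,
    preproc: PreprocConfig | None = None,
    fb_cfg: fb.FeedbackConfig | None = None,
    c_param: float = 1.0,
    keep_series: bool = False,
) -> SubjectRecord:
    """Run the full closed loop for one subject.

    Run 1 is feedback-free and trains the first decoder; each later run
    is decoded in real time volume-by-volume with the decoder trained on
    the previous run, feedback is displayed (contingent for NFB, seeded
    uniform-random for CTR), the latent state is updated from the mean
    displayed level over usable tenderness volumes, and the decoder is
    retrained on the just-completed run.
    """
    if n_runs < 2:
        raise ConfigError("closed loop needs n_runs >= 2")
    fb_cfg = fb_cfg or fb.FeedbackConfig(d_max=DISPLAY_D_MAX, seed=base_state.rng_seed)
    state = base_state
    sessions: list[SessionLog] = []
    series_kept: list[VolumeSeries] = []
    rng_ctr = np.random.default_rng(fb_cfg.seed + 7919)

    def _stream_features(series: VolumeSeries, labels):
        stream = VolumeStream(
            labels, atlas.feature_mask, atlas.grid.voxel_size_mm, preproc
        )
        feats = []
        for t in range(series.data.shape[0]):
            fv = stream.push(series.data[t])
            if fv is not None:
                feats.append(fv)
        return feats

    # run 1: training only
    design = make_default_design(start_condition, run_id=0, tr_seconds=atlas.grid.tr_seconds)
    labels = label_volumes(design)
    train_series = simulate_run(state, atlas, design, run_id=0)
    if keep_series:
        series_kept.append(train_series)
    current_decoder = dec.train_from_run(
        _stream_features(train_series, labels), c_param=c_param, trained_on=(0,)
    )

    for run_id in range(1, n_runs):
        design = make_default_design(start_condition, run_id=run_id, tr_seconds=atlas.grid.tr_seconds)
        labels = label_volumes(design)
        series = simulate_run(state, atlas, design, run_id=run_id)
        if keep_series:
            series_kept.append(series)
        feats = _stream_features(series, labels)

        rows = []
        predictions = {c.volume_index: Condition.NEUTRAL for c in labels}
        tend_levels: list[float] = []
        for fv in feats:
            d = current_decoder.decision_value(fv)
            predictions[fv.volume_index] = current_decoder.classify(fv)
            frame = fb.map_level(d, fv.condition, fb_cfg, volume_index=fv.volume_index)
            if state.group is Group.CTR:
                displayed = int(rng_ctr.integers(1, fb.N_LEVELS + 1))
                contingent = False
            else:
                displayed = frame.level
                contingent = True
            if fv.condition is Condition.TENDERNESS:
                tend_levels.append(displayed)
            rows.append(
                {
                    "volume_index": fv.volume_index,
                    "decision_value": d,
                    "target": fv.condition.value,
                    "correct": int(frame.correct),
                    "level": displayed,
                    "contingent": int(contingent),
                }
            )

        pred_list = [predictions[i] for i in range(design.n_volumes)]
        pct = pct_tenderness(pred_list, labels)
        n_tend = sum(
            1 for l in labels
            if l.usable_for_decoding and l.condition is Condition.TENDERNESS
        )
        hits = int(round(pct / 100.0 * n_tend))
        mean_level = float(np.mean(tend_levels)) if tend_levels else fb.MID_LEVEL
        sessions.append(
            SessionLog(
                run_id=run_id,
                frames=pd.DataFrame(rows),
                pct_tenderness=pct,
                tenderness_counts=(hits, n_tend),
                mean_displayed_level=mean_level,
            )
        )
        state = update_state(state, mean_level, contingent=state.group is Group.NFB)
        current_decoder = dec.train_from_run(feats, c_param=c_param, trained_on=(run_id,))

    outcome = SubjectOutcome(
        subject_id=subject_id,
        group=base_state.group,
        pct_tenderness_by_session=tuple(s.pct_tenderness for s in sessions),
        last_counts=sessions[-1].tenderness_counts,
    )
    return SubjectRecord(
        subject_id=subject_id,
        group=base_state.group,
        sessions=sessions,
        final_state=state,
        outcome=outcome,
        series=series_kept if keep_series else None,
    )


def simulate_cohort(
    n_per_group: int = 12,
    base_state: SubjectState = SubjectState(),
    n_runs: int = 4,
    seed: int = 0,
    atlas: PatternAtlas | None = None,
    nfb_learning_rate: float = DEFAULT_NFB_LEARNING_RATE,
    keep_series: bool = False,
    preproc: PreprocConfig | None = None,
) -> list[SubjectRecord]:
    """Simulate a two-group cohort through the full closed loop.

    NFB subjects learn at ``nfb_learning_rate``; CTR subjects share the
    same generative parameters but receive random rings and never update.
    Start condition is counterbalanced within each group.  Fully
    reproducible from ``seed``.
    """
    if n_runs < 2:
        raise ConfigError("n_runs >= 2 required")
    atlas = atlas or make_atlas(AcquisitionGrid(), seed=seed)
    master = np.random.default_rng(seed)
    records: list[SubjectRecord] = []
    for group in (Group.NFB, Group.CTR):
        for i in range(n_per_group):
            sub_seed = int(master.integers(0, 2**31 - 1))
            state = replace(
                base_state,
                group=group,
                rng_seed=sub_seed,
                learning_rate=nfb_learning_rate if group is Group.NFB else 0.0,
            )
            start = Condition.TENDERNESS if i % 2 == 0 else Condition.PRIDE
            records.append(
                simulate_subject(
                    state,
                    atlas,
                    n_runs=n_runs,
                    subject_id=f"sub-{group.value}{i:02d}",
                    start_condition=start,
                    preproc=preproc,
                    fb_cfg=fb.FeedbackConfig(d_max=DISPLAY_D_MAX, seed=sub_seed),
                    keep_series=keep_series,
                )
            )
    return records
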