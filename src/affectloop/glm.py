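"""Offline univariate block GLM and permutation small-volume correction.

Subject level: condition boxcars convolved with the canonical
double-gamma hemodynamic response, discrete-cosine high-pass drift
regressors inside the design (448 s cutoff by default), ordinary least
squares, tenderness - pride contrast.  Group level: per-voxel simple
regression of the contrast on a behavioural covariate, with family-wise
error control inside an a-priori region of interest by max-statistic
permutation of the covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import BlockDesign, Condition

HRF_PEAK_S = 6.0
HRF_UNDERSHOOT_S = 16.0
HRF_UNDERSHOOT_RATIO = 1.0 / 6.0
HRF_LENGTH_S = 32.0
HRF_DISPERSION = 1.0

DEFAULT_HP_CUTOFF_S = 448.0
CLUSTER_FORMING_P = 0.005


class GLMError(ValueError):
    pass


def hrf_kernel(tr_seconds: float) -> np.ndarray:
    """Canonical double-gamma HRF sampled at the TR, peak normalized to 1.

    Difference of two gamma densities: response peaking at 6 s minus an
    undershoot peaking at 16 s scaled by 1/6, over a 32 s support.
    """
    if tr_seconds <= 0:
        raise GLMError("tr must be positive")
    t = np.arange(0.0, HRF_LENGTH_S + tr_seconds / 2, tr_seconds)
    peak = sps.gamma.pdf(t, HRF_PEAK_S / HRF_DISPERSION, scale=HRF_DISPERSION)
    under = sps.gamma.pdf(t, HRF_UNDERSHOOT_S / HRF_DISPERSION, scale=HRF_DISPERSION)
    h = peak - HRF_UNDERSHOOT_RATIO * under
    return h / h.max()


def condition_boxcars(design: BlockDesign) -> dict[Condition, np.ndarray]:
    """Per-condition 0/1 indicator over the whole block duration."""
    n = design.n_volumes
    box = {c: np.zeros(n) for c in Condition}
    t = 0
    for blk in design.blocks:
        box[blk.condition][t : t + blk.n_volumes] = 1.0
        t += blk.n_volumes
    return box


def dct_drift_basis(n_volumes: int, tr_seconds: float, hp_cutoff_s: float) -> np.ndarray:
    """Discrete-cosine drift regressors for periods above the cutoff.

    K = floor(2 * T_total / cutoff) columns, the SPM high-pass convention.
    """
    if hp_cutoff_s <= 2 * tr_seconds:
        raise GLMError("cutoff must exceed twice the TR")
    n_k = int(np.floor(2.0 * n_volumes * tr_seconds / hp_cutoff_s))
    t = np.arange(n_volumes)
    basis = np.empty((n_volumes, n_k))
    for k in range(1, n_k + 1):
        basis[:, k - 1] = np.sqrt(2.0 / n_volumes) * np.cos(
            np.pi * k * (2 * t + 1) / (2.0 * n_volumes)
        )
    return basis


@dataclass(frozen=True)
class DesignMatrix:
    matrix: np.ndarray  # n_volumes x n_columns
    columns: tuple[str, ...]

    def column(self, name: str) -> int:
        return self.columns.index(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=list(self.columns))


def build_design(
    design: BlockDesign, hp_cutoff_s: float = DEFAULT_HP_CUTOFF_S
) -> DesignMatrix:
    """HRF-convolved condition regressors + DCT drift set + intercept.

    The neutral condition is the implicit baseline: only the two
    emotional regressors are modelled, so the design stays well
    conditioned (tenderness/pride/neutral boxcars sum to one at every
    volume and would be collinear with the intercept).
    """
    h = hrf_kernel(design.tr_seconds)
    box = condition_boxcars(design)
    n = design.n_volumes
    cols: list[np.ndarray] = []
    names: list[str] = []
    for cond in (Condition.TENDERNESS, Condition.PRIDE):
        reg = np.convolve(box[cond], h)[:n]
        if not reg.any():
            raise GLMError(f"no {cond.value} blocks in the design")
        cols.append(reg)
        names.append(cond.value)
    drift = dct_drift_basis(n, design.tr_seconds, hp_cutoff_s)
    for k in range(drift.shape[1]):
        cols.append(drift[:, k])
        names.append(f"dct_{k + 1}")
    # centered linear trend: scanner drift is locally linear and the DCT
    # set alone leaves a ramp residual that would leak into the betas
    t_axis = np.arange(n, dtype=float)
    cols.append(t_axis - t_axis.mean())
    names.append("trend")
    cols.append(np.ones(n))
    names.append("intercept")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise GLMError("rank-deficient design matrix")
    return DesignMatrix(X, tuple(names))


@dataclass(frozen=True)
class ContrastMap:
    """Voxel map of tenderness - pride contrast estimates for one subject."""

    data: np.ndarray  # 3D
    subject_id: str = ""


def fit_subject(series, X: DesignMatrix, subject_id: str = "") -> ContrastMap:
    """Voxelwise OLS betas; contrast = beta_tenderness - beta_pride.

    ``series`` is a VolumeSeries (time-first data) or a plain 4D array
    with time on the first axis.
    """
    data = series.data if hasattr(series, "data") else np.asarray(series, float)
    n_vol = data.shape[0]
    if X.matrix.shape[0] != n_vol:
        raise GLMError("design rows != run volumes")
    Y = data.reshape(n_vol, -1)
    beta, *_ = np.linalg.lstsq(X.matrix, Y, rcond=None)
    contrast = beta[X.column("tenderness")] - beta[X.column("pride")]
    return ContrastMap(contrast.reshape(data.shape[1:]), subject_id)


def _covariate_t(values: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Vectorized per-voxel slope t for regression on one covariate.

    ``values``: n_subjects x n_voxels; returns t with df = n - 2.
    Voxels with zero residual variance get t = 0.
    """
    n = covariate.size
    c = covariate - covariate.mean()
    sxx = float(c @ c)
    y = values - values.mean(axis=0)
    slope = (c @ y) / sxx
    resid = y - np.outer(c, slope)
    sse = np.einsum("ij,ij->j", resid, resid)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sse / (n - 2) / sxx)
        t = np.where(se > 0, slope / np.where(se > 0, se, 1.0), 0.0)
    return t


def second_level(
    contrasts: list[ContrastMap], covariate
) -> np.ndarray:
    """Covariate-slope t map (df = n - 2) from per-subject contrast maps."""
    cov = np.asarray(covariate, dtype=float)
    if len(contrasts) != cov.size:
        raise GLMError("covariate length != number of subjects")
    if len(contrasts) < 3:
        raise GLMError("need at least 3 subjects")
    if np.ptp(cov) == 0:
        raise GLMError("constant covariate")
    stack = np.asarray([c.data for c in contrasts], dtype=float)
    shape = stack.shape[1:]
    t = _covariate_t(stack.reshape(len(contrasts), -1), cov)
    return t.reshape(shape)


@dataclass(frozen=True)
class SVCResult:
    roi_name: str
    peak_stat: float
    peak_voxel: tuple[int, ...]
    cluster_size: int
    fwe_p: float
    degenerate: bool = False


def svc_correct(
    tmap: np.ndarray,
    roi: np.ndarray,
    contrasts: list[ContrastMap],
    covariate,
    n_perm: int = 1000,
    seed: int = 0,
    roi_name: str = "roi",
    forming_p: float = CLUSTER_FORMING_P,
) -> SVCResult:
    """Max-statistic permutation FWE within a region of interest.

    The covariate is permuted ``n_perm`` times; the null is the
    distribution of the ROI-maximum |t|.  fwe_p is the rank of the
    observed peak among the null maxima, (1 + #{null >= obs})/(n_perm+1).
    Cluster size counts ROI voxels whose positive t exceeds the
    uncorrected forming threshold (p < forming_p, one-sided).
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise GLMError("empty ROI")
    if n_perm < 100:
        raise GLMError("need n_perm >= 100")
    cov = np.asarray(covariate, dtype=float)
    n = cov.size
    stack = np.asarray([c.data for c in contrasts], dtype=float)
    roi_values = stack.reshape(n, -1)[:, roi.ravel()]

    t_roi = np.asarray(tmap)[roi]
    degenerate = bool(np.allclose(t_roi, 0))
    peak_flat = int(np.argmax(np.abs(t_roi)))
    peak_stat = float(t_roi[peak_flat])
    roi_coords = np.argwhere(roi)
    peak_voxel = tuple(int(v) for v in roi_coords[peak_flat])

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(cov)
        null_max[i] = np.max(np.abs(_covariate_t(roi_values, perm)))
    fwe_p = (1.0 + np.sum(null_max >= abs(peak_stat))) / (n_perm + 1.0)

    t_thresh = sps.t.isf(forming_p, df=n - 2)
    cluster_size = int(np.sum(t_roi > t_thresh))
    return SVCResult(
        roi_name=roi_name,
        peak_stat=peak_stat,
        peak_voxel=peak_voxel,
        cluster_size=cluster_size,
        fwe_p=float(fwe_p),
        degenerate=degenerate,
    )
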