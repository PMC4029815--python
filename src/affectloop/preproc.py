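"""Incremental (volume-by-volume) preprocessing for real-time decoding.

Stages, in order: optional translation-only realignment to a reference
volume, 3D Gaussian smoothing, subtraction of the voxelwise mean of the
most recent completed neutral block, and masked feature extraction.  The
pipeline is causal: the output for volume t depends only on volumes <= t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .design import Condition, VolumeLabel

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class ProtocolError(RuntimeError):
    """Stream consumed in an order the protocol does not allow."""


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PreprocConfig:
    """Real-time preprocessing parameters.

    fwhm_mm : Gaussian smoothing kernel full width at half maximum, mm.
    realign : estimate and undo rigid translation against the first volume.
    """

    fwhm_mm: float = 6.0
    realign: bool = False

    def __post_init__(self) -> None:
        if self.fwhm_mm < 0:
            raise ConfigError("fwhm_mm must be >= 0")


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    volume_index: int
    condition: Condition

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")


def smooth_volume(volume: np.ndarray, voxel_size_mm, fwhm_mm: float) -> np.ndarray:
    """Separable Gaussian smoothing with boundary renormalization.

    sigma per axis is fwhm/(2*sqrt(2 ln 2)) converted to voxel units.
    Reflective boundary handling preserves constant fields exactly.
    """
    if fwhm_mm < 0:
        raise ConfigError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return np.asarray(volume, dtype=float).copy()
    voxel_size_mm = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm
    return ndimage.gaussian_filter(
        np.asarray(volume, dtype=float), sigma=sigma_vox, mode="reflect", truncate=6.0
    )


def realign_translation(
    volume: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Translation-only realignment by cross-correlation peak.

    Returns the realigned volume and the estimated shift (voxels, the
    displacement of ``volume`` relative to ``reference``).  Sub-voxel
    precision comes from a quadratic fit around the integer peak; the
    volume is resampled back by the estimated shift with linear
    interpolation.
    """
    volume = np.asarray(volume, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if volume.shape != reference.shape:
        raise ValueError("volume and reference shapes differ")
    v = volume - volume.mean()
    r = reference - reference.mean()
    if np.allclose(v, 0) or np.allclose(r, 0):
        warnings.warn("flat volume: skipping realignment", RuntimeWarning, stacklevel=2)
        return volume.copy(), np.zeros(3)

    # circular cross-correlation via FFT; peak at the displacement of v vs r
    xc = np.fft.ifftn(np.fft.fftn(v) * np.conj(np.fft.fftn(r))).real
    peak = np.unravel_index(np.argmax(xc), xc.shape)
    shift = np.empty(3)
    for ax, p in enumerate(peak):
        n = xc.shape[ax]
        idx = [slice(pk, pk + 1) for pk in peak]
        y0 = xc[tuple(idx)].item()
        idx[ax] = slice((p - 1) % n, (p - 1) % n + 1)
        ym = xc[tuple(idx)].item()
        idx[ax] = slice((p + 1) % n, (p + 1) % n + 1)
        yp = xc[tuple(idx)].item()
        denom = ym - 2.0 * y0 + yp
        frac = 0.0 if abs(denom) < 1e-12 else 0.5 * (ym - yp) / denom
        s = p + frac
        if s > n / 2:  # wrap negative displacements
            s -= n
        shift[ax] = s
    realigned = ndimage.shift(volume, -shift, order=1, mode="nearest")
    return realigned, shift


def neutral_baseline(
    volumes: np.ndarray, labels: list[VolumeLabel], current_index: int
) -> np.ndarray:
    """Voxelwise mean over the most recent completed neutral block.

    ``volumes`` holds the per-volume lattices acquired so far (time first);
    only volumes strictly before ``current_index`` are consulted, keeping
    the stream causal.
    """
    # walk backwards to the last neutral volume, then span its block
    last_neutral = None
    for i in range(current_index - 1, -1, -1):
        if labels[i].condition is Condition.NEUTRAL:
            last_neutral = i
            break
    if last_neutral is None:
        raise ProtocolError(
            f"no neutral block precedes volume {current_index}"
        )
    block = labels[last_neutral].block_index
    members = [
        l.volume_index
        for l in labels
        if l.block_index == block and l.volume_index < current_index
    ]
    return np.mean(np.asarray(volumes)[members], axis=0)


def extract_features(
    volume: np.ndarray,
    baseline: np.ndarray,
    mask: np.ndarray,
    volume_index: int = -1,
    condition: Condition = Condition.NEUTRAL,
) -> FeatureVector:
    """Masked normalized signal, in fixed row-major (x, y, z) voxel order."""
    volume = np.asarray(volume, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not (volume.shape == baseline.shape == mask.shape):
        raise ValueError("volume, baseline, and mask shapes differ")
    if not mask.any():
        raise ConfigError("feature mask is empty")
    diff = volume - baseline
    return FeatureVector(diff[mask], volume_index, condition)


class VolumeStream:
    """Stateful streaming front-end: one raw volume in, one processed out.

    Feeds volumes through realignment (against the first volume) and
    smoothing, retaining the processed history needed by the neutral
    baseline.  Feature vectors are produced only for usable volumes.
    """

    def __init__(
        self,
        labels: list[VolumeLabel],
        mask: np.ndarray,
        voxel_size_mm=(3.0, 3.0, 3.0),
        config: PreprocConfig | None = None,
    ):
        self.labels = labels
        self.mask = np.asarray(mask, dtype=bool)
        self.voxel_size_mm = voxel_size_mm
        self.config = config or PreprocConfig()
        self._history: list[np.ndarray] = []
        self._reference: np.ndarray | None = None

    @property
    def next_index(self) -> int:
        return len(self._history)

    def push(self, volume: np.ndarray) -> FeatureVector | None:
        """Process the next volume; returns features if it is usable."""
        t = self.next_index
        if t >= len(self.labels):
            raise ProtocolError("more volumes than the design specifies")
        vol = np.asarray(volume, dtype=float)
        if self.config.realign:
            if self._reference is None:
                self._reference = vol
            else:
                vol, _ = realign_translation(vol, self._reference)
        vol = smooth_volume(vol, self.voxel_size_mm, self.config.fwhm_mm)
        self._history.append(vol)
        label = self.labels[t]
        if not label.usable_for_decoding:
            return None
        baseline = neutral_baseline(self._history, self.labels, t)
        return extract_features(vol, baseline, self.mask, t, label.condition)
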