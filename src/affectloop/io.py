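"""On-disk formats: NIfTI volumes and masks, TSV tables, run manifests."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .design import BlockDesign, write_design_tsv, write_labels_tsv
from .simulate import AcquisitionGrid, SubjectRecord, VolumeSeries


class ManifestError(RuntimeError):
    pass


def _affine(grid: AcquisitionGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = grid.voxel_size_mm
    return aff


def write_series_nifti(series: VolumeSeries, path: str | Path) -> None:
    """4D NIfTI, spatial axes first (x, y, z, t)."""
    data = np.moveaxis(series.data, 0, -1)
    img = nib.Nifti1Image(data.astype(np.float32), _affine(series.grid))
    img.header["pixdim"][4] = series.grid.tr_seconds
    nib.save(img, str(path))


def read_series_nifti(
    path: str | Path, design: BlockDesign, run_id: int = 0
) -> VolumeSeries:
    img = nib.load(str(path))
    data = np.moveaxis(np.asanyarray(img.dataobj, dtype=float), -1, 0)
    voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
    grid = AcquisitionGrid(
        dims=data.shape[1:], voxel_size_mm=voxel, tr_seconds=design.tr_seconds
    )
    return VolumeSeries(grid, data, run_id, design)


def write_mask_nifti(mask: np.ndarray, grid: AcquisitionGrid, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), _affine(grid)), str(path))


def read_mask_nifti(path: str | Path) -> np.ndarray:
    return np.asanyarray(nib.load(str(path)).dataobj) > 0


def write_weight_map_nifti(
    w: np.ndarray, mask: np.ndarray, grid: AcquisitionGrid, path: str | Path
) -> None:
    """Unflatten decoder weights onto the grid through the feature mask."""
    vol = np.zeros(grid.dims, dtype=np.float32)
    vol[np.asarray(mask, bool)] = w
    nib.save(nib.Nifti1Image(vol, _affine(grid)), str(path))


def write_feedback_log(frames: pd.DataFrame, path: str | Path) -> None:
    frames.to_csv(path, sep="\t", index=False)


@dataclass
class RunManifest:
    """Paths and identities of one simulated cohort on disk."""

    root: Path
    subjects: list[dict] = field(default_factory=list)  # id, group, runs, logs
    mask_path: str = "feature_mask.nii.gz"
    roi_path: str = "svc_roi.nii.gz"
    design_paths: list[str] = field(default_factory=list)
    seed: int = 0
    notes: list[str] = field(default_factory=list)

    def save(self, path: str | Path | None = None) -> Path:
        path = Path(path) if path else self.root / "manifest.yaml"
        payload = {
            "seed": self.seed,
            "mask": self.mask_path,
            "svc_roi": self.roi_path,
            "designs": self.design_paths,
            "subjects": self.subjects,
            "notes": self.notes,
        }
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        path = Path(path)
        payload = yaml.safe_load(path.read_text())
        m = cls(
            root=path.parent,
            subjects=payload["subjects"],
            mask_path=payload["mask"],
            roi_path=payload["svc_roi"],
            design_paths=payload["designs"],
            seed=payload["seed"],
            notes=payload.get("notes", []),
        )
        m.validate()
        return m

    def validate(self) -> None:
        missing = []
        for rel in [self.mask_path, self.roi_path, *self.design_paths]:
            if not (self.root / rel).exists():
                missing.append(rel)
        for sub in self.subjects:
            for rel in sub.get("runs", []) + sub.get("feedback_logs", []):
                if not (self.root / rel).exists():
                    missing.append(rel)
        if missing:
            raise ManifestError(f"missing files: {missing}")


def export_cohort(
    records: list[SubjectRecord],
    atlas,
    out_dir: str | Path,
    seed: int,
    write_runs: bool = True,
) -> RunManifest:
    """Write a simulated cohort (runs, masks, designs, logs) plus manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(root=out, seed=seed)
    write_mask_nifti(atlas.feature_mask, atlas.grid, out / manifest.mask_path)
    write_mask_nifti(atlas.svc_roi, atlas.grid, out / manifest.roi_path)

    for rec in records:
        sub_dir = out / rec.subject_id
        sub_dir.mkdir(exist_ok=True)
        entry = {
            "id": rec.subject_id,
            "group": rec.group.value,
            "runs": [],
            "feedback_logs": [],
            "pct_tenderness_by_session": [s.pct_tenderness for s in rec.sessions],
        }
        if write_runs and rec.series:
            for series in rec.series:
                rel = f"{rec.subject_id}/run-{series.run_id}.nii.gz"
                write_series_nifti(series, out / rel)
                entry["runs"].append(rel)
                design_rel = f"{rec.subject_id}/run-{series.run_id}_design.tsv"
                write_design_tsv(series.design, out / design_rel)
                labels_rel = f"{rec.subject_id}/run-{series.run_id}_labels.tsv"
                write_labels_tsv(series.design, out / labels_rel)
                if design_rel not in manifest.design_paths:
                    manifest.design_paths.append(design_rel)
        for sess in rec.sessions:
            rel = f"{rec.subject_id}/session-{sess.run_id}_feedback.tsv"
            write_feedback_log(sess.frames, out / rel)
            entry["feedback_logs"].append(rel)
        manifest.subjects.append(entry)

    n_sessions = min(
        (len(s["feedback_logs"]) for s in manifest.subjects), default=0
    )
    if n_sessions == 0:
        manifest.notes.append("no classification sessions")
    manifest.save()
    return manifest
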