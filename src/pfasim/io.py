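"""File interchange: NIfTI label/float volumes, CSV traces, JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .scenario import ScenarioGrid
from .study_metrics import SegmentationVolume

__all__ = [
    "save_grid_nifti",
    "load_grid_nifti",
    "save_volume_nifti",
    "save_segmentation_nifti",
    "load_segmentation_nifti",
    "save_trace_csv",
    "save_waveform_csv",
    "write_json",
]


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def save_grid_nifti(grid: ScenarioGrid, path: str | Path) -> None:
    """Integer label volume plus a JSON sidecar with spacing, electrode
    levels and builder metadata."""
    path = Path(path)
    s = grid.spacing_mm
    img = nib.Nifti1Image(grid.labels.astype(np.int16), _affine((s, s, s)))
    nib.save(img, str(path))
    sidecar = {
        "spacing_mm": s,
        "electrode_voltage": {str(k): v for k, v in grid.electrode_voltage.items()},
        "meta": grid.meta,
    }
    path.with_suffix("").with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True)
    )


def load_grid_nifti(path: str | Path) -> ScenarioGrid:
    path = Path(path)
    img = nib.load(str(path))
    sidecar = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    return ScenarioGrid(
        spacing_mm=float(sidecar["spacing_mm"]),
        labels=np.asarray(img.dataobj, dtype=np.int8),
        electrode_voltage={int(k): v for k, v in sidecar["electrode_voltage"].items()},
        meta=sidecar.get("meta", {}),
    )


def save_volume_nifti(
    volume: np.ndarray, spacing_mm: float, path: str | Path
) -> None:
    """Float volume (potential, field magnitude, peak temperature...)."""
    img = nib.Nifti1Image(
        np.asarray(volume, dtype=np.float32), _affine((spacing_mm,) * 3)
    )
    nib.save(img, str(Path(path)))


def save_segmentation_nifti(seg: SegmentationVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(seg.labels.astype(np.int16), _affine(seg.voxel_size_mm))
    nib.save(img, str(Path(path)))


def load_segmentation_nifti(path: str | Path) -> SegmentationVolume:
    img = nib.load(str(Path(path)))
    zooms = img.header.get_zooms()[:3]
    return SegmentationVolume(
        labels=np.asarray(img.dataobj, dtype=np.int8),
        voxel_size_mm=(float(zooms[0]), float(zooms[1]), float(zooms[2])),
    )


def save_trace_csv(times_s: np.ndarray, columns: dict, path: str | Path) -> None:
    """Probe series to CSV: time_s plus one column per probe."""
    pd.DataFrame({"time_s": times_s, **columns}).to_csv(Path(path), index=False)


def save_waveform_csv(times_s: np.ndarray, volts: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"time_s": times_s, "value": volts}).to_csv(Path(path), index=False)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
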