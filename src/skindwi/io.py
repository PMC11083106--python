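"""Disk I/O for DWI studies, masks, manifests and result tables.

Conventions fixed at this API boundary:

* volume arrays are ``(x, y, z, b)`` with 0-based voxel indexing,
  regardless of on-disk orientation; orientation (affine) matrices are
  carried through untouched,
* masks are binarized at ``> 0`` (label exports store small integers),
* volumes are stored as float32 NIfTI-1, masks as uint8 NIfTI-1,
* b-values live in an FSL-style ``.bval`` file (whitespace-separated)
  or a JSON sidecar with a ``"b_values"`` key.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "DWIStudy",
    "VOIMask",
    "read_bvals",
    "write_bvals",
    "read_dwi_study",
    "write_dwi_study",
    "read_mask",
    "write_mask",
    "read_manifest",
    "write_manifest",
    "write_results",
]


class DataError(ValueError):
    """Raised for invalid or inconsistent on-disk / in-memory data."""


@dataclass
class DWIStudy:
    """One subject's multi-b-value diffusion-weighted image stack.

    Parameters
    ----------
    volumes
        4D signal array, axes ``(x, y, z, b)``; non-negative.
    b_values
        Diffusion weightings in s/mm^2, aligned to the 4th axis.
    voxel_spacing
        Voxel edge lengths in mm.
    case_id
        Subject identifier.
    group
        Optional cohort group label.
    affine
        NIfTI orientation matrix, passed through unmodified.
    """

    volumes: np.ndarray
    b_values: tuple[float, ...]
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    case_id: str = ""
    group: str | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.volumes.ndim != 4:
            raise DataError(
                f"DWI stack must be 4D (x, y, z, b); got {self.volumes.ndim}D"
            )
        if any(s < 1 for s in self.volumes.shape[:3]):
            raise DataError("spatial dimensions must all be >= 1")
        self.b_values = tuple(float(b) for b in self.b_values)
        if len(self.b_values) != self.volumes.shape[3]:
            raise DataError(
                f"{len(self.b_values)} b-values for "
                f"{self.volumes.shape[3]} volumes"
            )
        if np.any(self.volumes < 0):
            raise DataError("negative signal intensities are not allowed")
        self.voxel_spacing = tuple(float(v) for v in self.voxel_spacing)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.volumes.shape[:3]

    def volume_at(self, b_value: float) -> np.ndarray:
        """Return the 3D volume acquired at ``b_value``."""
        for i, b in enumerate(self.b_values):
            if np.isclose(b, b_value):
                return self.volumes[..., i]
        raise DataError(
            f"b-value {b_value} not in study (available: {self.b_values})"
        )


@dataclass
class VOIMask:
    """Binary voxel set congruent with a study's spatial grid."""

    data: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data) > 0
        if self.data.ndim != 3:
            raise DataError(f"mask must be 3D; got {self.data.ndim}D")
        if not self.data.any():
            raise DataError("empty VOI: mask selects no voxels")

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    def check_congruent(self, study: DWIStudy) -> None:
        if self.data.shape != study.spatial_shape:
            raise DataError(
                f"mask shape {self.data.shape} does not match study "
                f"spatial shape {study.spatial_shape}"
            )


# --------------------------------------------------------------------------
# b-value metadata


def read_bvals(path: str | Path) -> tuple[float, ...]:
    """Parse an FSL-style ``.bval`` file (whitespace-separated numbers)."""
    text = Path(path).read_text().split()
    if not text:
        raise DataError(f"no b-values found in {path}")
    return tuple(float(tok) for tok in text)


def write_bvals(b_values: Sequence[float], path: str | Path) -> None:
    Path(path).write_text(
        " ".join(format(b, "g") for b in b_values) + "\n"
    )


def _read_sidecar_bvals(path: str | Path) -> tuple[float, ...]:
    meta = json.loads(Path(path).read_text())
    if "b_values" not in meta:
        raise DataError(f"sidecar {path} has no 'b_values' key")
    return tuple(float(b) for b in meta["b_values"])


# --------------------------------------------------------------------------
# NIfTI volumes and masks


def read_dwi_study(
    image_path: str | Path,
    bval_path: str | Path | None = None,
    sidecar_path: str | Path | None = None,
    case_id: str | None = None,
    group: str | None = None,
) -> DWIStudy:
    """Load a 4D NIfTI stack plus b-value metadata into a validated study.

    Exactly one of ``bval_path`` / ``sidecar_path`` must be given.
    """
    if (bval_path is None) == (sidecar_path is None):
        raise DataError("provide exactly one of bval_path or sidecar_path")
    img = nib.load(str(image_path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 4:
        raise DataError(
            f"{image_path}: expected a 4D image, got {data.ndim}D"
        )
    b_values = (
        read_bvals(bval_path)
        if bval_path is not None
        else _read_sidecar_bvals(sidecar_path)
    )
    zooms = img.header.get_zooms()[:3]
    return DWIStudy(
        volumes=data,
        b_values=b_values,
        voxel_spacing=tuple(float(z) for z in zooms),
        case_id=case_id or Path(image_path).name.split(".")[0],
        group=group,
        affine=np.asarray(img.affine),
    )


def write_dwi_study(
    study: DWIStudy,
    image_path: str | Path,
    bval_path: str | Path | None = None,
    sidecar_path: str | Path | None = None,
    sidecar_extra: Mapping[str, object] | None = None,
) -> None:
    """Write a study as float32 NIfTI plus .bval and/or JSON sidecar."""
    affine = study.affine.copy()
    img = nib.Nifti1Image(study.volumes.astype(np.float32), affine)
    img.header.set_zooms(study.voxel_spacing + (1.0,))
    nib.save(img, str(image_path))
    if bval_path is not None:
        write_bvals(study.b_values, bval_path)
    if sidecar_path is not None:
        meta: dict[str, object] = {
            "case_id": study.case_id,
            "group": study.group,
            "b_values": list(study.b_values),
            "voxel_spacing_mm": list(study.voxel_spacing),
        }
        if sidecar_extra:
            meta.update(sidecar_extra)
        Path(sidecar_path).write_text(json.dumps(meta, indent=1))


def read_mask(path: str | Path, study: DWIStudy | None = None) -> VOIMask:
    """Load a mask NIfTI, binarize at > 0 and optionally shape-check."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise DataError(f"{path}: mask must be 3D, got {data.ndim}D")
    mask = VOIMask(data=data, name=Path(path).name.split(".")[0])
    if study is not None:
        mask.check_congruent(study)
    return mask


def write_mask(
    mask: VOIMask, path: str | Path, affine: np.ndarray | None = None
) -> None:
    img = nib.Nifti1Image(
        mask.data.astype(np.uint8), np.eye(4) if affine is None else affine
    )
    nib.save(img, str(path))


# --------------------------------------------------------------------------
# manifests and result tables

MANIFEST_COLUMNS = [
    "case_id",
    "group",
    "image",
    "bval",
    "mask",
    "noise_roi",
]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV; file paths resolve relative to the CSV."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"manifest {path} missing columns: {missing}")
    base = Path(path).parent
    for col in ("image", "bval", "mask", "noise_roi"):
        df[col] = [
            str(base / p) if p and not Path(p).is_absolute() else p
            for p in df[col].fillna("")
        ]
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    run_report: Mapping[str, object] | None = None,
) -> dict[str, Path]:
    """Write result tables as CSV and the run report as JSON.

    Returns a mapping from table name to the path written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in tables.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        written[name] = p
    if run_report is not None:
        p = out / "run_report.json"
        p.write_text(json.dumps(run_report, indent=1, default=str))
        written["run_report"] = p
    return written
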