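"""I/O layer and subject-level inclusion rules.

Reads and writes the on-disk formats the pipeline touches: NIfTI-1 volumes
(4-D BOLD series and 3-D tissue/atlas maps), 6-column motion-parameter text
files, the tab-separated atlas label table, and the cohort-manifest CSV.
Also implements the subject-level preprocessing decisions that operate on
whole files: discarding lead-in frames and the head-motion exclusion rule
(exclude when any translation exceeds 2 mm or any rotation exceeds 1 degree).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Volume4D",
    "BrainMask",
    "AtlasParcellation",
    "MotionTrace",
    "CohortManifest",
    "MotionDecision",
    "load_volume4d",
    "save_volume4d",
    "load_volume3d",
    "save_volume3d",
    "discard_initial_volumes",
    "motion_exclusion",
    "make_brain_mask",
    "load_motion_trace",
    "save_motion_trace",
    "load_label_table",
    "default_label_table",
    "load_atlas",
    "save_atlas",
    "load_manifest",
    "save_manifest",
]

DEFAULT_MAX_TRANSLATION_MM = 2.0
DEFAULT_MAX_ROTATION_DEG = 1.0


class DimensionalityError(ValueError):
    """Raised when a volume does not have the expected number of axes."""


class FormatError(ValueError):
    """Raised when a file cannot be parsed as the expected format."""


@dataclass
class Volume4D:
    """A preprocessed BOLD series on a regular grid.

    ``data`` is indexed (x, y, z, t); ``voxel_size`` is in mm and ``tr``
    (the repetition time, i.e. the sampling interval of the series) in
    seconds.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise DimensionalityError(
                f"expected a 4-D series, got {self.data.ndim} axes"
            )
        if self.n_timepoints < 2:
            raise ValueError("a time series needs at least 2 frames")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class BrainMask:
    """Boolean support grid aligned to a reference volume."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise DimensionalityError("mask must be 3-D")
        if not self.mask.any():
            raise ValueError("mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class AtlasParcellation:
    """Integer label volume plus the id -> (name, abbreviation) table.

    Label 0 is background and never a region. ``table`` is a DataFrame with
    columns label_id, name, abbreviation, ordered as features are emitted.
    """

    labels: np.ndarray
    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise DimensionalityError("atlas label volume must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        required = {"label_id", "name", "abbreviation"}
        if not required.issubset(self.table.columns):
            raise FormatError(f"label table needs columns {sorted(required)}")
        ids = self.table["label_id"].to_numpy()
        if len(np.unique(ids)) != len(ids) or (ids <= 0).any():
            raise ValueError("label_ids must be unique and positive")
        present = np.unique(self.labels)
        present = present[present != 0]
        missing = np.setdiff1d(present, ids)
        if missing.size:
            raise ValueError(f"labels in volume missing from table: {missing}")

    @property
    def region_ids(self) -> np.ndarray:
        return self.table["label_id"].to_numpy()

    @property
    def abbreviations(self) -> list[str]:
        return list(self.table["abbreviation"])

    @property
    def n_regions(self) -> int:
        return len(self.table)


@dataclass
class MotionTrace:
    """Per-frame rigid-body motion estimates.

    ``params`` has one row per frame and 6 columns: 3 translations (mm)
    followed by 3 rotations. Rotations are in degrees by default; pass
    ``rotation_unit='rad'`` and they are converted on construction.
    """

    params: np.ndarray
    rotation_unit: str = "deg"

    def __post_init__(self) -> None:
        self.params = np.atleast_2d(np.asarray(self.params, dtype=float))
        if self.params.shape[0] == 0:
            raise ValueError("motion trace is empty")
        if self.params.shape[1] != 6:
            raise FormatError("motion trace needs 6 columns")
        if self.rotation_unit == "rad":
            self.params = self.params.copy()
            self.params[:, 3:] = np.degrees(self.params[:, 3:])
            self.rotation_unit = "deg"
        elif self.rotation_unit != "deg":
            raise ValueError("rotation_unit must be 'deg' or 'rad'")

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]

    @property
    def translations(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations(self) -> np.ndarray:
        return self.params[:, 3:]


@dataclass
class MotionDecision:
    keep: bool
    offending_axis: str | None = None


MANIFEST_COLUMNS = [
    "subject_id",
    "group",
    "path_bold",
    "path_gm",
    "path_wm",
    "path_csf",
    "path_motion",
]


@dataclass
class CohortManifest:
    """Table of subjects and the files belonging to each."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(MANIFEST_COLUMNS) - set(self.records.columns)
        if missing:
            raise FormatError(f"manifest missing columns {sorted(missing)}")
        ids = self.records["subject_id"]
        if ids.duplicated().any():
            raise ValueError("subject_ids must be unique")
        groups = set(self.records["group"])
        if not {"case", "control"}.issubset(groups):
            raise ValueError("manifest must contain both groups")

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# NIfTI volumes


def load_volume4d(path: str | Path, tr: float | None = None) -> Volume4D:
    """Load a 4-D NIfTI series.

    TR precedence: an explicit ``tr`` argument (manifest/config) overrides
    the header timing field, because synthetic fixtures may carry default
    headers.
    """
    img = _load_nifti(path)
    if img.ndim != 4:
        raise DimensionalityError(f"{path}: expected 4-D, got {img.ndim}-D")
    data = np.asarray(img.dataobj, dtype=np.float64)
    zooms = img.header.get_zooms()
    voxel_size = tuple(float(z) for z in zooms[:3])
    header_tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    return Volume4D(data=data, voxel_size=voxel_size,
                    tr=tr if tr is not None else header_tr)


def save_volume4d(vol: Volume4D, path: str | Path,
                  dtype: np.dtype | type = np.float32) -> None:
    affine = np.diag(list(vol.voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=dtype), affine)
    img.header.set_zooms(tuple(vol.voxel_size) + (vol.tr,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def load_volume3d(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Load a 3-D NIfTI map; returns (data, voxel_size_mm)."""
    img = _load_nifti(path)
    if img.ndim != 3:
        raise DimensionalityError(f"{path}: expected 3-D, got {img.ndim}-D")
    data = np.asarray(img.dataobj, dtype=np.float64)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, voxel_size


def save_volume3d(data: np.ndarray, path: str | Path,
                  voxel_size: Sequence[float] = (1.0, 1.0, 1.0),
                  dtype: np.dtype | type = np.float32) -> None:
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=dtype), affine), str(path))


def _load_nifti(path: str | Path):
    try:
        return nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc


# ---------------------------------------------------------------------------
# Frame discarding and motion exclusion


def discard_initial_volumes(vol: Volume4D, k: int) -> Volume4D:
    """Drop the first ``k`` frames (signal-equilibration lead-in)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if k >= vol.n_timepoints:
        raise ValueError(
            f"discarding {k} frames would empty a {vol.n_timepoints}-frame series"
        )
    if k == 0:
        return vol
    return Volume4D(data=vol.data[..., k:], voxel_size=vol.voxel_size, tr=vol.tr)


def motion_exclusion(trace: MotionTrace,
                     max_trans_mm: float = DEFAULT_MAX_TRANSLATION_MM,
                     max_rot_deg: float = DEFAULT_MAX_ROTATION_DEG) -> MotionDecision:
    """Apply the per-axis head-motion exclusion rule.

    A subject is excluded when the absolute maximum over frames of any single
    translation axis exceeds ``max_trans_mm`` or of any rotation axis exceeds
    ``max_rot_deg``. "Maximum displacement in any direction" is read
    per-axis, not as a Euclidean norm.
    """
    if max_trans_mm <= 0 or max_rot_deg <= 0:
        raise ValueError("thresholds must be positive")
    trans = np.abs(trace.translations).max(axis=0)
    rot = np.abs(trace.rotations).max(axis=0)
    axes = ["trans_x", "trans_y", "trans_z"]
    for i in range(3):
        if trans[i] > max_trans_mm:
            return MotionDecision(keep=False, offending_axis=axes[i])
    axes = ["rot_x", "rot_y", "rot_z"]
    for i in range(3):
        if rot[i] > max_rot_deg:
            return MotionDecision(keep=False, offending_axis=axes[i])
    return MotionDecision(keep=True)


def make_brain_mask(volume: Volume4D | np.ndarray,
                    fraction: float = 0.2) -> BrainMask:
    """Threshold-based brain support.

    Voxels whose temporal mean (or value, for a 3-D map) exceeds
    ``fraction`` of the volume's robust maximum (98th percentile) are kept.
    This provides the explicit support over which global means (the ALFF and
    ReHo normalisation divisors) are taken.
    """
    if isinstance(volume, Volume4D):
        ref = volume.data.mean(axis=3)
    else:
        ref = np.asarray(volume, dtype=float)
        if ref.ndim != 3:
            raise DimensionalityError("expected a 3-D map or a Volume4D")
    robust_max = np.percentile(ref, 98)
    mask = ref > fraction * robust_max
    if not mask.any():
        raise ValueError("brain mask is empty (all-background volume?)")
    return BrainMask(mask=mask)


# ---------------------------------------------------------------------------
# Motion files, label tables, atlases, manifests


def load_motion_trace(path: str | Path, rotation_unit: str = "deg") -> MotionTrace:
    """Read a whitespace-delimited 6-column motion-parameter file."""
    try:
        params = np.loadtxt(str(path), ndmin=2)
    except Exception as exc:
        raise FormatError(f"cannot parse motion file {path}: {exc}") from exc
    return MotionTrace(params=params, rotation_unit=rotation_unit)


def save_motion_trace(trace: MotionTrace, path: str | Path) -> None:
    np.savetxt(str(path), trace.params, fmt="%.6f")


def load_label_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"label_id", "name", "abbreviation"}
    if not required.issubset(table.columns):
        raise FormatError(f"label table needs columns {sorted(required)}")
    return table


def default_label_table() -> pd.DataFrame:
    """The shipped 116-region AAL-style label table.

    90 cerebral regions (45 left/right pairs), 18 cerebellar-hemisphere
    regions (9 pairs) and 8 vermis regions.
    """
    ref = importlib.resources.files("pdmri").joinpath("data/aal116_labels.tsv")
    with importlib.resources.as_file(ref) as p:
        return load_label_table(p)


def load_atlas(label_volume_path: str | Path,
               table: pd.DataFrame | str | Path | None = None) -> AtlasParcellation:
    """Load an atlas label volume; defaults to the shipped 116-entry table."""
    img = _load_nifti(label_volume_path)
    if img.ndim != 3:
        raise DimensionalityError("atlas label volume must be 3-D")
    labels = np.asarray(img.dataobj).astype(np.int32)
    if table is None:
        table = default_label_table()
    elif not isinstance(table, pd.DataFrame):
        table = load_label_table(table)
    return AtlasParcellation(labels=labels, table=table)


def save_atlas(atlas: AtlasParcellation, volume_path: str | Path,
               table_path: str | Path | None = None,
               voxel_size: Sequence[float] = (1.0, 1.0, 1.0)) -> None:
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int32), affine),
             str(volume_path))
    if table_path is not None:
        atlas.table.to_csv(table_path, sep="\t", index=False)


def load_manifest(path: str | Path) -> CohortManifest:
    records = pd.read_csv(path, dtype={"subject_id": str})
    return CohortManifest(records=records)


def save_manifest(manifest: CohortManifest, path: str | Path) -> None:
    manifest.records.to_csv(path, index=False, columns=MANIFEST_COLUMNS)
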