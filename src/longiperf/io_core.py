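"""Volumes, masks, cohort manifests and feature tables.

All imaging data move through two light containers, :class:`Volume` and
:class:`Mask`, backed by NIfTI-1 files on disk.  A cohort is described by a
:class:`CohortManifest` (CSV or JSON, one row per subject/time-point) which
mirrors the two-arm design of longitudinal glioma surveillance studies:
subjects with a single perfusion time point versus subjects with multiple
(2-3) time points.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger("longiperf")

#: Canonical acquisition sequences, in table order.
SEQUENCES = ("T1", "T1Gad", "T2", "FLAIR", "rCBV", "rCBF")
STRUCTURAL_SEQUENCES = ("T1", "T1Gad", "T2", "FLAIR")
PERFUSION_SEQUENCES = ("rCBV", "rCBF")

#: The three modelled response categories.
CLASS_LABELS = ("PD", "PsP", "SD")

MANIFEST_PATH_COLUMNS = tuple(f"path_{s}" for s in SEQUENCES) + (
    "path_lesion",
    "path_reference",
)


class VolumeError(ValueError):
    """Raised for unreadable, non-3-D or NaN-contaminated volumes."""


class ManifestError(ValueError):
    """Raised for structurally invalid cohort manifests."""


class FeatureTableError(ValueError):
    """Raised for inconsistent feature vectors."""


def configure_logging(log_file: str | Path | None = None, level: int = logging.INFO) -> None:
    """Route pipeline logs to stderr and, optionally, a run-log file."""
    logger.setLevel(level)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    logger.addHandler(sh)
    if log_file is not None:
        fh = logging.FileHandler(log_file)
        fh.setFormatter(fmt)
        logger.addHandler(fh)


@dataclass
class Volume:
    """A 3-D scalar image on a regular grid.

    Parameters
    ----------
    data : ndarray
        3-D floating point voxel array (arbitrary units).
    spacing : tuple of float
        Voxel size in mm per axis; strictly positive.
    origin : tuple of float
        World-space position of voxel (0, 0, 0) in mm.
    orientation : str
        Axis-direction codes, e.g. ``"RAS"``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise VolumeError(f"volume must be 3-D, got shape {self.data.shape}")
        if any(s <= 0 for s in self.spacing):
            raise VolumeError(f"non-positive spacing {self.spacing}")
        if np.isnan(self.data).any():
            raise VolumeError("volume contains NaN voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def same_grid(self, other: "Volume | Mask") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


@dataclass
class Mask:
    """A binary region on the grid of a companion :class:`Volume`.

    ``role`` is one of ``lesion`` (the segmented abnormality), ``reference``
    (the deep-grey normalisation region) or ``brain``.
    """

    data: np.ndarray
    role: str = "lesion"
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data) > 0.5
        if self.data.ndim != 3:
            raise VolumeError(f"mask must be 3-D, got shape {self.data.shape}")
        if self.role in ("lesion", "reference") and not self.data.any():
            raise VolumeError(f"{self.role} mask has no foreground voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class StudyTimePoint:
    """All sequences plus masks for one subject at one time point."""

    subject_id: str
    time_point: int
    day: int
    volumes: dict[str, Volume]
    lesion: Mask
    reference: Mask

    def __post_init__(self) -> None:
        missing = [s for s in SEQUENCES if s not in self.volumes]
        if missing:
            raise VolumeError(f"missing sequences {missing} for {self.subject_id}")
        ref_vol = self.volumes[SEQUENCES[0]]
        for name, vol in self.volumes.items():
            if not ref_vol.same_grid(vol):
                raise VolumeError(
                    f"{self.subject_id} tp{self.time_point}: sequence {name} "
                    f"is not on the common grid"
                )
        for m in (self.lesion, self.reference):
            if m.shape != ref_vol.shape:
                raise VolumeError(
                    f"{self.subject_id} tp{self.time_point}: {m.role} mask "
                    f"shape {m.shape} != volume shape {ref_vol.shape}"
                )


def read_volume(path: str | Path) -> Volume:
    """Load a 3-D NIfTI-1 volume, promoting integer types to float.

    Raises :class:`VolumeError` (naming the path) for a missing file, a
    non-3-D image, or NaN voxels.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeError(f"no such volume file: {path}")
    img = nib.load(str(path))
    if img.ndim != 3:
        raise VolumeError(f"non-3-D image ({img.ndim}-D): {path}")
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if np.isnan(data).any():
        raise VolumeError(f"NaN voxels in volume: {path}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    orientation = "".join(nib.aff2axcodes(img.affine))
    return Volume(data=data, spacing=zooms, origin=origin, orientation=orientation)


def write_volume(vol: Volume, path: str | Path) -> Path:
    """Persist a :class:`Volume` as NIfTI-1 (float64, loss-free round trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(vol.data.astype(np.float64), vol.affine())
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path, role: str = "lesion") -> Mask:
    vol = read_volume(path)
    return Mask(data=vol.data, role=role, spacing=vol.spacing, origin=vol.origin)


def write_mask(mask: Mask, path: str | Path) -> Path:
    vol = Volume(
        data=mask.data.astype(np.float64), spacing=mask.spacing, origin=mask.origin
    )
    return write_volume(vol, path)


@dataclass
class CohortManifest:
    """Validated cohort description: one row per (subject, time point).

    Subjects split into a single-time-point group and a multi-time-point
    group (>= 2 perfusion time points), mirroring surveillance cohorts where
    only a subset of patients receives repeat perfusion imaging.
    """

    table: pd.DataFrame
    base_dir: Path | None = None

    REQUIRED = ("subject_id", "time_point", "day", "class_label")

    def __post_init__(self) -> None:
        df = self.table
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ManifestError(f"manifest missing required column '{col}'")
        bad = set(df["class_label"]) - set(CLASS_LABELS)
        if bad:
            raise ManifestError(
                f"unknown class label(s) {sorted(bad)}; expected one of {CLASS_LABELS}"
            )
        if "rater_label" in df.columns:
            rater = df["rater_label"].dropna()
            bad = set(rater) - set(CLASS_LABELS)
            if bad:
                raise ManifestError(f"unknown rater label(s) {sorted(bad)}")
        if df.duplicated(["subject_id", "time_point"]).any():
            dups = df[df.duplicated(["subject_id", "time_point"], keep=False)]
            raise ManifestError(
                f"duplicate (subject, time_point) rows: "
                f"{dups[['subject_id', 'time_point']].values.tolist()}"
            )
        for sid, grp in df.groupby("subject_id"):
            tps = sorted(int(t) for t in grp["time_point"])
            if tps != list(range(1, len(tps) + 1)):
                raise ManifestError(
                    f"gap in time-point indices for subject {sid}: {tps}"
                )
            if grp["class_label"].nunique() != 1:
                raise ManifestError(f"class_label varies within subject {sid}")

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.table["subject_id"]))

    @property
    def multi_timepoint_subjects(self) -> list[str]:
        counts = self.table.groupby("subject_id")["time_point"].size()
        return [s for s in self.subjects if counts[s] >= 2]

    @property
    def single_timepoint_subjects(self) -> list[str]:
        counts = self.table.groupby("subject_id")["time_point"].size()
        return [s for s in self.subjects if counts[s] == 1]

    def class_label(self, subject_id: str) -> str:
        rows = self.table[self.table["subject_id"] == subject_id]
        return str(rows["class_label"].iloc[0])

    def rater_label(self, subject_id: str) -> str | None:
        if "rater_label" not in self.table.columns:
            return None
        rows = self.table[self.table["subject_id"] == subject_id]
        v = rows["rater_label"].iloc[0]
        return None if pd.isna(v) else str(v)

    def resolve(self, rel: str) -> Path:
        p = Path(rel)
        if not p.is_absolute() and self.base_dir is not None:
            p = self.base_dir / p
        return p

    def load_study(self, subject_id: str, time_point: int) -> StudyTimePoint:
        rows = self.table[
            (self.table["subject_id"] == subject_id)
            & (self.table["time_point"] == time_point)
        ]
        if rows.empty:
            raise ManifestError(f"no manifest row for {subject_id} tp{time_point}")
        row = rows.iloc[0]
        volumes = {s: read_volume(self.resolve(row[f"path_{s}"])) for s in SEQUENCES}
        lesion = read_mask(self.resolve(row["path_lesion"]), role="lesion")
        reference = read_mask(self.resolve(row["path_reference"]), role="reference")
        return StudyTimePoint(
            subject_id=subject_id,
            time_point=int(row["time_point"]),
            day=int(row["day"]),
            volumes=volumes,
            lesion=lesion,
            reference=reference,
        )


def read_manifest(path: str | Path, check_files: bool = True) -> CohortManifest:
    """Read and validate a cohort manifest (CSV, or JSON list-of-rows)."""
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"no such manifest: {path}")
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            df = pd.DataFrame(json.load(fh))
    else:
        df = pd.read_csv(path)
    manifest = CohortManifest(table=df, base_dir=path.parent)
    if check_files:
        for col in MANIFEST_PATH_COLUMNS:
            if col not in df.columns:
                raise ManifestError(f"manifest missing file column '{col}'")
            for rel in df[col]:
                p = manifest.resolve(str(rel))
                if not p.exists():
                    raise ManifestError(f"referenced file does not exist: {p}")
    logger.info(
        "manifest %s: %d subjects (%d single-tp, %d multi-tp)",
        path.name,
        len(manifest.subjects),
        len(manifest.single_timepoint_subjects),
        len(manifest.multi_timepoint_subjects),
    )
    return manifest


def write_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(manifest.table.to_dict(orient="records"), indent=1))
    else:
        manifest.table.to_csv(path, index=False)
    return path


@dataclass
class FeatureVector:
    """Named scalar radiomic features for one subject."""

    subject_id: str
    features: dict[str, float]
    class_label: str | None = None
    rater_label: str | None = None

    def __post_init__(self) -> None:
        for name, v in self.features.items():
            if v is not None and not np.isfinite(v):
                raise FeatureTableError(
                    f"{self.subject_id}: non-finite feature {name} = {v}"
                )


def write_feature_table(
    vectors: Sequence[FeatureVector], path: str | Path
) -> pd.DataFrame:
    """Write one row per subject, one column per feature, to CSV.

    Vectors may lack subtraction (``Diff*``) features — single-time-point
    subjects — which are written as empty cells; any other naming mismatch is
    an error.  Floats round-trip at full double precision.
    """
    if not vectors:
        raise FeatureTableError("no feature vectors to write")
    names: list[str] = []
    for v in vectors:
        for n in v.features:
            if n not in names:
                names.append(n)
    for v in vectors:
        missing = [n for n in names if n not in v.features]
        non_diff = [n for n in missing if not n.startswith("Diff")]
        if non_diff:
            raise FeatureTableError(
                f"{v.subject_id} lacks non-subtraction features {non_diff[:5]}; "
                "vectors must share one feature-name set"
            )
    rows = []
    for v in vectors:
        row: dict[str, object] = {
            "subject_id": v.subject_id,
            "class_label": v.class_label,
            "rater_label": v.rater_label,
        }
        row.update({n: v.features.get(n, np.nan) for n in names})
        rows.append(row)
    df = pd.DataFrame(rows)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")
    logger.info("feature table %s: %d subjects x %d features", path, len(df), len(names))
    return df


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if "subject_id" not in df.columns:
        raise FeatureTableError(f"not a feature table (no subject_id): {path}")
    return df
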