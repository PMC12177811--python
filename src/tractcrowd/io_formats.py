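"""Streamline, scalar-volume and subject-table I/O.

All streamline coordinates are world millimetres in RAS orientation
internally; format-specific conventions (TRK's voxel-based storage) are
converted at the I/O boundary.  Scalar volumes carry their voxel-to-world
affine and are sampled with trilinear interpolation; out-of-volume samples
yield NaN and are excluded from downstream means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel.streamlines import Tractogram
from nibabel.streamlines.tck import TckFile
from nibabel.streamlines.trk import TrkFile

from tractcrowd.errors import EmptyBundleError, FormatError, SchemaError

#: A streamline is an ordered (V, 3) float array of world-mm RAS points.
Streamline = np.ndarray

_REQUIRED_SUBJECT_COLUMNS = (
    "subject_id",
    "group",
    "contralesional_hemisphere",
    "etiology",
    "viq",
    "piq",
    "age_at_scan",
    "age_at_surgery",
    "age_at_onset",
    "skeleton_mean_fa",
)


def as_streamline(points: Sequence | np.ndarray) -> Streamline:
    """Validate and coerce ``points`` into a (V, 3) float64 streamline.

    Raises
    ------
    ValueError
        If fewer than two vertices, non-finite coordinates, or all
        consecutive vertices coincide.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"streamline must be (V, 3), got {pts.shape}")
    if pts.shape[0] < 2:
        raise ValueError("streamline needs at least 2 vertices")
    if not np.all(np.isfinite(pts)):
        raise ValueError("streamline contains non-finite coordinates")
    seg = np.diff(pts, axis=0)
    if np.all(np.linalg.norm(seg, axis=1) == 0.0):
        raise ValueError("streamline is degenerate: all vertices identical")
    return pts


@dataclass
class Bundle:
    """A named collection of streamlines from one subject and hemisphere."""

    streamlines: list[Streamline]
    subject_id: str = ""
    hemisphere: str = "left"
    tract_name: str = ""

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be left/right, got {self.hemisphere!r}")
        self.streamlines = [as_streamline(s) for s in self.streamlines]

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def with_streamlines(self, streamlines: Iterable[np.ndarray]) -> "Bundle":
        """Copy of this bundle with replaced streamlines, same labels."""
        return Bundle(
            streamlines=list(streamlines),
            subject_id=self.subject_id,
            hemisphere=self.hemisphere,
            tract_name=self.tract_name,
        )

    @property
    def n_vertices(self) -> int:
        return int(sum(len(s) for s in self.streamlines))


@dataclass
class ScalarVolume:
    """A 3-D scalar grid with a voxel-to-world affine."""

    grid: np.ndarray
    affine: np.ndarray
    metric_name: str = "FA"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.grid.ndim != 3:
            raise ValueError("grid must be 3-D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")


@dataclass
class SubjectRecord:
    """Clinical and cognitive covariates for one participant."""

    subject_id: str
    group: str
    contralesional_hemisphere: str = "n/a"
    etiology: str = "n/a"
    viq: float = math.nan
    piq: float = math.nan
    age_at_scan: float = math.nan
    age_at_surgery: float = math.nan
    age_at_onset: float = math.nan
    skeleton_mean_fa: float = math.nan
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ValueError(f"group must be patient/control, got {self.group!r}")
        if self.contralesional_hemisphere not in ("left", "right", "n/a"):
            raise ValueError(
                "contralesional_hemisphere must be left/right/n/a, "
                f"got {self.contralesional_hemisphere!r}"
            )
        if self.etiology not in ("congenital", "acquired", "n/a"):
            raise ValueError(f"etiology must be congenital/acquired/n/a, got {self.etiology!r}")


def read_streamlines(path: str | Path, dialect: str | None = None) -> Bundle:
    """Load a TCK or TRK file into a :class:`Bundle` in world-mm RAS.

    Parameters
    ----------
    path
        File path; extension decides the dialect unless ``dialect`` is given.
    dialect
        ``"tck"`` or ``"trk"``; overrides extension sniffing.

    Raises
    ------
    FormatError
        Malformed or truncated file.
    EmptyBundleError
        File parses but holds zero streamlines.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = path.suffix.lstrip(".").lower()
    cls = {"tck": TckFile, "trk": TrkFile}.get(dialect)
    if cls is None:
        raise FormatError(f"unknown streamline dialect {dialect!r}")
    try:
        tf = cls.load(str(path), lazy_load=False)
    except Exception as exc:  # nibabel raises assorted header/data errors
        raise FormatError(f"cannot parse {path} as {dialect}: {exc}") from exc
    # nibabel tractograms are exposed in RAS+ mm regardless of on-disk convention
    streamlines = [np.asarray(s, dtype=np.float64) for s in tf.tractogram.streamlines]
    if len(streamlines) == 0:
        raise EmptyBundleError(f"{path} holds no streamlines")
    subject_id, hemisphere, tract = _parse_bundle_name(path.stem)
    return Bundle(
        streamlines=streamlines,
        subject_id=subject_id,
        hemisphere=hemisphere,
        tract_name=tract,
    )


def write_streamlines(
    bundle: Bundle,
    path: str | Path,
    dialect: str | None = None,
    affine: np.ndarray | None = None,
) -> Path:
    """Write a bundle to TCK or TRK.

    ``affine`` (voxel-to-world) is only relevant for TRK, whose on-disk
    convention is voxel-based; points are converted from world mm on save
    and back on load.  Defaults to identity.
    """
    path = Path(path)
    if dialect is None:
        dialect = path.suffix.lstrip(".").lower()
    tractogram = Tractogram(bundle.streamlines, affine_to_rasmm=np.eye(4))
    if dialect == "tck":
        TckFile(tractogram).save(str(path))
    elif dialect == "trk":
        header = {}
        if affine is not None:
            header[nib.streamlines.trk.Field.VOXEL_TO_RASMM] = np.asarray(affine, dtype=np.float64)
            header[nib.streamlines.trk.Field.VOXEL_SIZES] = np.linalg.norm(
                np.asarray(affine)[:3, :3], axis=0
            )
        TrkFile(tractogram, header=header).save(str(path))
    else:
        raise FormatError(f"unknown streamline dialect {dialect!r}")
    return path


def _parse_bundle_name(stem: str) -> tuple[str, str, str]:
    """Best-effort ``sub-XXX_hemi-left_TRACT`` filename convention parser."""
    subject_id, hemisphere, tract = "", "left", ""
    for part in stem.split("_"):
        if part.startswith("sub-"):
            subject_id = part[4:]
        elif part.startswith("hemi-") and part[5:] in ("left", "right"):
            hemisphere = part[5:]
        else:
            tract = part
    return subject_id, hemisphere, tract


def read_scalar_volume(path: str | Path, metric_name: str = "FA") -> ScalarVolume:
    """Load a NIfTI scalar map."""
    img = nib.load(str(path))
    return ScalarVolume(
        grid=np.asarray(img.get_fdata(), dtype=np.float64),
        affine=np.asarray(img.affine, dtype=np.float64),
        metric_name=metric_name,
    )


def write_scalar_volume(volume: ScalarVolume, path: str | Path) -> Path:
    path = Path(path)
    nib.Nifti1Image(volume.grid.astype(np.float32), volume.affine).to_filename(str(path))
    return path


def sample_scalar_at_points(volume: ScalarVolume, points: np.ndarray) -> np.ndarray:
    """Trilinearly sample ``volume`` at world-mm ``points``.

    Points outside the grid yield NaN (missing-value marker), never raise.
    Sampling a field that is affine in world coordinates reproduces the
    field exactly at interior points.
    """
    from scipy.ndimage import map_coordinates

    pts = np.asarray(points, dtype=np.float64)
    squeeze = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if not np.all(np.isfinite(pts)):
        raise ValueError("sample points must be finite")
    inv = np.linalg.inv(volume.affine)
    vox = pts @ inv[:3, :3].T + inv[:3, 3]
    out = map_coordinates(
        volume.grid, vox.T, order=1, mode="constant", cval=np.nan, prefilter=False
    )
    # guard: coordinates strictly beyond the voxel-centre hull are missing
    shape = np.array(volume.grid.shape, dtype=np.float64)
    outside = np.any((vox < 0.0) | (vox > shape - 1.0), axis=1)
    out = np.where(outside, np.nan, out)
    return out[0] if squeeze else out


def read_subjects(path: str | Path) -> list[SubjectRecord]:
    """Read the subject metadata TSV into typed records.

    Required columns: ``subject_id, group, contralesional_hemisphere,
    etiology, viq, piq, age_at_scan, age_at_surgery, age_at_onset,
    skeleton_mean_fa``.  Unknown columns are preserved under ``extras``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    missing = [c for c in _REQUIRED_SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"subject table is missing columns: {missing}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise SchemaError(f"duplicate subject_id values: {dupes}")
    extras_cols = [c for c in df.columns if c not in _REQUIRED_SUBJECT_COLUMNS]
    records = []
    for _, row in df.iterrows():
        try:
            rec = SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]).strip().lower(),
                contralesional_hemisphere=_norm_cat(row["contralesional_hemisphere"]),
                etiology=_norm_cat(row["etiology"]),
                viq=_as_float(row["viq"], "viq", row["subject_id"]),
                piq=_as_float(row["piq"], "piq", row["subject_id"]),
                age_at_scan=_as_float(row["age_at_scan"], "age_at_scan", row["subject_id"]),
                age_at_surgery=_as_float(
                    row["age_at_surgery"], "age_at_surgery", row["subject_id"]
                ),
                age_at_onset=_as_float(row["age_at_onset"], "age_at_onset", row["subject_id"]),
                skeleton_mean_fa=_as_float(
                    row["skeleton_mean_fa"], "skeleton_mean_fa", row["subject_id"]
                ),
                extras={c: row[c] for c in extras_cols},
            )
        except ValueError as exc:
            raise SchemaError(str(exc)) from exc
        records.append(rec)
    return records


def write_subjects(records: Sequence[SubjectRecord], path: str | Path) -> Path:
    """Write subject records to TSV, inverse of :func:`read_subjects`."""
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in _REQUIRED_SUBJECT_COLUMNS}
        row.update(r.extras)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return Path(path)


def _norm_cat(value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "n/a"
    s = str(value).strip().lower()
    return "n/a" if s in ("", "na", "n/a", "nan", "none") else s


def _as_float(value, column: str, subject) -> float:
    if value is None or (isinstance(value, str) and value.strip() == ""):
        return math.nan
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise ValueError(
            f"non-numeric value {value!r} in column {column} for subject {subject}"
        ) from exc
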