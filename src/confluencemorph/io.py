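"""Labeled segmentation volumes and clinical cohort tables.

Everything downstream of the segmentation step consumes exactly two in-memory
containers defined here: :class:`LabelVolume` (an axis-aligned 3D integer label
grid with physical voxel spacing, world units mm) and :class:`PatientRecord`
(clinical covariates plus the right-censored postsurgical pulmonary vein
stenosis outcome). Files never cross a module boundary.

Conventions
-----------
* 0-based voxel indices; world coordinate of index (i, j, k) is
  ``origin + (i*sx, j*sy, k*sz)``. Oblique orientations must be resampled
  before entry; readers reject non-axis-aligned affines.
* Lengths in mm, volumes reported downstream in cm^3, body surface area (BSA)
  in m^2. BSA is an input, never computed from height/weight.
* Default label schema assigns 1..7 to LA, PVC, LUPV, RUPV, LIPV, RIPV, VV.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk

__all__ = [
    "Role",
    "LabelSchema",
    "LabelVolume",
    "PatientRecord",
    "SchemaViolationError",
    "FormatError",
    "CohortValidationError",
    "read_label_volume",
    "write_label_volume",
    "read_cohort_table",
    "write_cohort_table",
    "cohort_summary",
]


class Role(str, enum.Enum):
    """Anatomical structures of the supracardiac TAPVC label map."""

    LA = "LA"        # left atrium
    PVC = "PVC"      # pulmonary venous confluence (the common channel)
    LUPV = "LUPV"    # left upper pulmonary vein
    RUPV = "RUPV"    # right upper pulmonary vein
    LIPV = "LIPV"    # left inferior pulmonary vein
    RIPV = "RIPV"    # right inferior pulmonary vein
    VV = "VV"        # vertical vein


#: venous structures (everything except the atrium)
VENOUS_ROLES = (Role.PVC, Role.LUPV, Role.RUPV, Role.LIPV, Role.RIPV, Role.VV)


class SchemaViolationError(ValueError):
    """A voxel value or schema entry violates the label schema."""


class FormatError(ValueError):
    """The on-disk volume is not a 3D integer label map with usable metadata."""


class CohortValidationError(ValueError):
    """A cohort table row violates the clinical-record contract."""


@dataclasses.dataclass(frozen=True)
class LabelSchema:
    """Mapping from anatomical role to integer label value.

    The default assigns 1..7 in the order LA, PVC, LUPV, RUPV, LIPV, RIPV, VV.
    All seven roles must be present and the labels distinct positive integers;
    supracardiac inputs without a vertical vein are not valid for this tool.
    """

    labels: Mapping[Role, int] = dataclasses.field(
        default_factory=lambda: {r: i + 1 for i, r in enumerate(Role)}
    )

    def __post_init__(self) -> None:
        missing = [r for r in Role if r not in self.labels]
        if missing:
            raise SchemaViolationError(f"schema missing roles: {missing}")
        vals = [int(self.labels[r]) for r in Role]
        if len(set(vals)) != len(vals):
            raise SchemaViolationError(f"schema labels not distinct: {vals}")
        if any(v <= 0 for v in vals):
            raise SchemaViolationError(f"schema labels must be positive: {vals}")

    def __getitem__(self, role: Role) -> int:
        return int(self.labels[role])

    @property
    def values(self) -> frozenset[int]:
        return frozenset(int(self.labels[r]) for r in Role)

    def role_of(self, value: int) -> Role:
        for r in Role:
            if int(self.labels[r]) == int(value):
                return r
        raise SchemaViolationError(f"no role for label value {value}")


@dataclasses.dataclass
class LabelVolume:
    """Axis-aligned 3D integer label grid in physical (mm) coordinates."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    schema: LabelSchema = dataclasses.field(default_factory=LabelSchema)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise FormatError(f"label volume must be 3D, got ndim={self.voxels.ndim}")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise FormatError(f"label volume must be integer, got {self.voxels.dtype}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        self.origin = tuple(float(o) for o in self.origin)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(
            not np.isfinite(s) or s <= 0 for s in self.spacing
        ):
            raise FormatError(f"spacing must be 3 positive finite numbers: {self.spacing}")
        self.validate_labels()

    def validate_labels(self) -> None:
        present = set(np.unique(self.voxels).tolist())
        allowed = {0} | set(self.schema.values)
        unknown = sorted(present - allowed)
        if unknown:
            raise SchemaViolationError(
                f"unknown label value(s) {unknown} not in schema {sorted(allowed)}"
            )

    # -- coordinate contract -------------------------------------------------
    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """World mm coordinates of (fractional) voxel indices, shape (..., 3)."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        world = np.asarray(world, dtype=float)
        return (world - np.asarray(self.origin)) / np.asarray(self.spacing)

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def mask(self, role: Role) -> np.ndarray:
        """Boolean mask of one structure."""
        return self.voxels == self.schema[role]

    def count(self, role: Role) -> int:
        return int(self.mask(role).sum())


@dataclasses.dataclass
class PatientRecord:
    """One subject: identifiers, covariates, and the censored outcome.

    ``time_months`` is the time from the index repair to postsurgical
    pulmonary vein stenosis (PPVS) when ``event`` is true, otherwise the
    censoring time. Extra table columns are retained in ``covariates``.
    """

    id: str
    age_days: float
    bsa_m2: float
    prepvo: bool
    time_months: float
    event: bool
    covariates: dict[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.time_months) or self.time_months < 0:
            raise CohortValidationError(
                f"record {self.id!r}: time_months must be >= 0, got {self.time_months}"
            )
        if not np.isfinite(self.bsa_m2) or self.bsa_m2 <= 0:
            raise CohortValidationError(
                f"record {self.id!r}: bsa_m2 must be > 0, got {self.bsa_m2}"
            )
        if not np.isfinite(self.age_days) or self.age_days < 0:
            raise CohortValidationError(
                f"record {self.id!r}: age_days must be >= 0, got {self.age_days}"
            )


# ---------------------------------------------------------------------------
# volume I/O
# ---------------------------------------------------------------------------

def _check_axis_aligned(affine: np.ndarray, path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Return (spacing, origin) from a diagonal-up-to-sign affine, else raise."""
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.abs(off_diag).max() > 1e-6 * max(1.0, np.abs(rot).max()):
        raise FormatError(
            f"{path}: oblique orientation; resample to an axis-aligned grid first"
        )
    spacing = np.abs(np.diag(rot))
    origin = affine[:3, 3]
    return spacing, origin


def read_label_volume(path: str | Path, schema: LabelSchema | None = None) -> LabelVolume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) label map.

    The file must contain a 3D integer array on an axis-aligned grid; voxel
    values must lie in {0} plus the schema labels, otherwise a
    :class:`SchemaViolationError` naming the offending value is raised.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    schema = schema or LabelSchema()
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if not np.issubdtype(data.dtype, np.integer):
            if not np.allclose(data, np.round(data)):
                raise FormatError(f"{path}: voxel data is not integer-valued")
            data = np.round(data).astype(np.int64)
        spacing, origin = _check_axis_aligned(np.asarray(img.affine), path)
    elif suffixes.endswith((".mha", ".mhd")):
        img = sitk.ReadImage(str(path))
        if img.GetDimension() != 3:
            raise FormatError(f"{path}: expected 3D image, got {img.GetDimension()}D")
        direction = np.asarray(img.GetDirection()).reshape(3, 3)
        if np.abs(direction - np.eye(3)).max() > 1e-6:
            raise FormatError(
                f"{path}: oblique orientation; resample to an axis-aligned grid first"
            )
        arr = sitk.GetArrayFromImage(img)  # (z, y, x)
        if not np.issubdtype(arr.dtype, np.integer):
            raise FormatError(f"{path}: voxel data is not integer-valued")
        data = np.transpose(arr, (2, 1, 0))
        spacing = np.asarray(img.GetSpacing())
        origin = np.asarray(img.GetOrigin())
    else:
        raise FormatError(f"{path}: unsupported volume format (use .nii[.gz]/.mha)")
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3D volume, got ndim={data.ndim}")
    return LabelVolume(
        voxels=data.astype(np.uint8, casting="unsafe")
        if data.max(initial=0) < 256 and data.min(initial=0) >= 0
        else data,
        spacing=tuple(float(s) for s in spacing),
        origin=tuple(float(o) for o in origin),
        schema=schema,
    )


def write_label_volume(vol: LabelVolume, path: str | Path) -> Path:
    """Write a label map; round-trips voxels, spacing, and origin exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = vol.voxels.astype(np.uint8)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        affine = np.eye(4)
        affine[:3, :3] = np.diag(vol.spacing)
        affine[:3, 3] = vol.origin
        nib.save(nib.Nifti1Image(data, affine), str(path))
    elif suffixes.endswith((".mha", ".mhd")):
        img = sitk.GetImageFromArray(np.transpose(data, (2, 1, 0)))
        img.SetSpacing(tuple(vol.spacing))
        img.SetOrigin(tuple(vol.origin))
        sitk.WriteImage(img, str(path))
    else:
        raise FormatError(f"{path}: unsupported volume format (use .nii[.gz]/.mha)")
    return path


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("id", "age_days", "bsa_m2", "prepvo", "time_months", "event")


def read_cohort_table(path: str | Path) -> list[PatientRecord]:
    """Read a cohort CSV (header ``id,age_days,bsa_m2,prepvo,time_months,event``).

    Booleans are encoded 0/1. Extra columns are retained per record in the
    covariate map (numeric where possible). Row indices in error messages are
    0-based data rows (excluding the header).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{path}: missing required column(s) {missing}")
    if df["id"].astype(str).duplicated().any():
        dupes = df["id"][df["id"].astype(str).duplicated()].tolist()
        raise CohortValidationError(f"{path}: duplicate id(s) {dupes}")
    extras = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    records: list[PatientRecord] = []
    for i, row in df.iterrows():
        try:
            rec = PatientRecord(
                id=str(row["id"]),
                age_days=float(row["age_days"]),
                bsa_m2=float(row["bsa_m2"]),
                prepvo=bool(int(row["prepvo"])),
                time_months=float(row["time_months"]),
                event=bool(int(row["event"])),
                covariates={
                    c: (float(row[c]) if pd.api.types.is_number(row[c]) else row[c])
                    for c in extras
                },
            )
        except CohortValidationError as exc:
            raise CohortValidationError(f"{path}: row {i}: {exc}") from exc
        records.append(rec)
    return records


def write_cohort_table(records: Sequence[PatientRecord], path: str | Path) -> Path:
    """Write records to CSV in the canonical column layout (booleans as 0/1)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    extras: list[str] = []
    for r in records:
        for k in r.covariates:
            if k not in extras:
                extras.append(k)
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "age_days": r.age_days,
            "bsa_m2": r.bsa_m2,
            "prepvo": int(r.prepvo),
            "time_months": r.time_months,
            "event": int(r.event),
        }
        row.update({k: r.covariates.get(k, np.nan) for k in extras})
        rows.append(row)
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + extras).to_csv(path, index=False)
    return path


def cohort_summary(records: Sequence[PatientRecord]) -> dict[str, float]:
    """Descriptive summary: size, event count/percentage, median follow-up."""
    n = len(records)
    if n == 0:
        raise CohortValidationError("empty cohort")
    events = sum(r.event for r in records)
    times = np.array([r.time_months for r in records])
    return {
        "n": float(n),
        "n_events": float(events),
        "event_pct": 100.0 * events / n,
        "median_time_months": float(np.median(times)),
        "median_event_time_months": float(
            np.median([r.time_months for r in records if r.event])
        )
        if events
        else float("nan"),
    }
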