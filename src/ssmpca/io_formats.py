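"""NIfTI volume and cohort-manifest I/O shared by all pipeline stages.

All subject data enters the pipeline as :class:`VoxelImage` volumes referenced
from a tab-separated cohort manifest. Grids (shape + affine) must match exactly
across a cohort; resampling is out of scope, so any mismatch is an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

GROUP_REFERENCE = "reference"
GROUP_TARGET = "target"
VALID_GROUPS = (GROUP_REFERENCE, GROUP_TARGET)

MANIFEST_COLUMNS = ["subject_id", "group", "modality", "image_path", "gm_path", "wm_path"]


@dataclass
class VoxelImage:
    """A 3-D scalar field on a fixed grid with spatial metadata."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    n_nonfinite: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        self.n_nonfinite = int(np.count_nonzero(~np.isfinite(self.data)))

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]


@dataclass
class Subject:
    """One subject: group label, one image per modality, GM/WM probability maps."""

    subject_id: str
    group: str
    images: dict[str, VoxelImage]
    gm: VoxelImage
    wm: VoxelImage

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValueError(f"group must be one of {VALID_GROUPS}, got {self.group!r}")


@dataclass
class Cohort:
    """A set of co-registered subjects sharing one grid."""

    subjects: list[Subject]

    @property
    def modalities(self) -> list[str]:
        names: list[str] = []
        for s in self.subjects:
            for m in s.images:
                if m not in names:
                    names.append(m)
        return names

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.subjects[0].gm.shape

    def ids(self, group: str | None = None) -> list[str]:
        return [s.subject_id for s in self.subjects if group is None or s.group == group]

    def subset(self, subject_ids: list[str]) -> "Cohort":
        wanted = set(subject_ids)
        return Cohort(subjects=[s for s in self.subjects if s.subject_id in wanted])


def read_volume(path: str | Path) -> VoxelImage:
    """Read a NIfTI-1/2 volume; non-finite voxels are counted, not altered."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise ValueError(f"unreadable NIfTI volume at {path}: {exc}") from exc
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    return VoxelImage(data=data, affine=np.asarray(img.affine))


def write_volume(image: VoxelImage, path: str | Path) -> Path:
    """Write a volume as NIfTI-1. Deterministic: identical inputs give identical bytes."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nifti = nib.Nifti1Image(image.data.astype(np.float64), image.affine)
    nifti.header.set_data_dtype(np.float64)
    nib.save(nifti, str(path))
    return path


def write_manifest(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write per-subject volumes and a TSV manifest describing them."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.subjects:
        gm_path = out_dir / f"{s.subject_id}_gm.nii.gz"
        wm_path = out_dir / f"{s.subject_id}_wm.nii.gz"
        write_volume(s.gm, gm_path)
        write_volume(s.wm, wm_path)
        for modality, image in s.images.items():
            img_path = out_dir / f"{s.subject_id}_{modality}.nii.gz"
            write_volume(image, img_path)
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "modality": modality,
                    "image_path": img_path.name,
                    "gm_path": gm_path.name,
                    "wm_path": wm_path.name,
                }
            )
    manifest_path = out_dir / "manifest.tsv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest_path, sep="\t", index=False)
    return manifest_path


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Load and validate a cohort manifest (TSV with header).

    Checks: required columns, (subject_id, modality) uniqueness, valid group
    labels, referenced files exist, and grid consistency across all volumes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns: {missing}")
    dup = table.duplicated(subset=["subject_id", "modality"])
    if dup.any():
        offenders = table.loc[dup, ["subject_id", "modality"]].to_records(index=False).tolist()
        raise ValueError(f"duplicate (subject_id, modality) rows in manifest: {offenders}")
    bad_groups = sorted(set(table["group"]) - set(VALID_GROUPS))
    if bad_groups:
        raise ValueError(f"invalid group labels {bad_groups}; expected one of {VALID_GROUPS}")
    base = path.parent
    shapes: dict[tuple[int, int, int], str] = {}
    for _, row in table.iterrows():
        for col in ("image_path", "gm_path", "wm_path"):
            p = base / row[col]
            if not p.exists():
                raise FileNotFoundError(f"manifest references missing file: {p}")
            shape = nib.load(str(p)).shape[:3]
            shapes.setdefault(tuple(shape), str(p))
    if len(shapes) > 1:
        raise ValueError(f"inconsistent grids across manifest volumes: {sorted(shapes)}")
    return table


def load_cohort(manifest_path: str | Path) -> Cohort:
    """Materialise a :class:`Cohort` from a validated manifest."""
    manifest_path = Path(manifest_path)
    table = load_manifest(manifest_path)
    base = manifest_path.parent
    subjects: dict[str, Subject] = {}
    for _, row in table.iterrows():
        sid = row["subject_id"]
        if sid not in subjects:
            subjects[sid] = Subject(
                subject_id=sid,
                group=row["group"],
                images={},
                gm=read_volume(base / row["gm_path"]),
                wm=read_volume(base / row["wm_path"]),
            )
        subjects[sid].images[row["modality"]] = read_volume(base / row["image_path"])
    return Cohort(subjects=list(subjects.values()))


def check_common_grid(images: list[VoxelImage], names: list[str] | None = None) -> None:
    """Raise if any image disagrees with the first on shape, naming the offender."""
    if not images:
        return
    ref = images[0].shape
    for i, img in enumerate(images):
        if img.shape != ref:
            who = names[i] if names else f"image {i}"
            raise ValueError(f"grid mismatch: {who} has shape {img.shape}, expected {ref}")
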