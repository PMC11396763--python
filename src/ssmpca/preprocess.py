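"""Analysis-mask construction and intensity normalisation.

The whole-brain mask keeps voxels carrying grey- or white-matter information;
by default a voxel is retained only if GM+WM probability exceeds the threshold
for *every* subject (intersection), so each cell of the data matrix is
brain-supported for each subject. Globally scaled contrasts (T1w/T2w/FLAIR-like)
are divided by their in-mask mean; intrinsically normalised quantitative maps
(MTR/qMT-like) are used as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import Cohort, VoxelImage, check_common_grid

NORM_GLOBAL_MEAN = "global_mean"
NORM_NONE = "none"

MASK_INTERSECTION = "intersection"
MASK_UNION = "union"


@dataclass
class BrainMask:
    """Boolean analysis mask on the common grid.

    Voxel order of every matrix built from this mask is the ascending linear
    index of the mask in the image's native (C-order) axis layout; stable
    across calls so saved patterns stay interpretable.
    """

    mask: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def indices(self) -> np.ndarray:
        """Flat voxel indices in ascending order — the column order contract."""
        return np.flatnonzero(self.mask.ravel(order="C"))

    def flatten(self, image: VoxelImage) -> np.ndarray:
        if image.shape != tuple(self.mask.shape):
            raise ValueError(f"image grid {image.shape} does not match mask {self.mask.shape}")
        return image.data.ravel(order="C")[self.indices]

    def embed(self, values: np.ndarray, fill: float = 0.0) -> VoxelImage:
        """Re-embed a voxel vector into the 3-D grid (inverse of :meth:`flatten`)."""
        values = np.asarray(values, dtype=np.float64)
        if values.shape != (self.n_voxels,):
            raise ValueError(f"expected {self.n_voxels} values, got {values.shape}")
        flat = np.full(self.mask.size, fill, dtype=np.float64)
        flat[self.indices] = values
        return VoxelImage(flat.reshape(self.mask.shape))


@dataclass
class DataMatrix:
    """Subjects × in-mask voxels with row bookkeeping; the PCA input container."""

    matrix: np.ndarray
    subject_ids: list[str]
    group_labels: np.ndarray
    mask: BrainMask

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.group_labels = np.asarray(self.group_labels, dtype=object)
        if self.matrix.shape[0] != len(self.subject_ids):
            raise ValueError("row count does not match subject_ids")
        if self.matrix.shape[0] != len(self.group_labels):
            raise ValueError("row count does not match group_labels")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    def rows_for(self, group: str) -> np.ndarray:
        return self.matrix[self.group_labels == group]

    def subset(self, row_indices: np.ndarray) -> "DataMatrix":
        idx = np.asarray(row_indices)
        return DataMatrix(
            matrix=self.matrix[idx],
            subject_ids=[self.subject_ids[i] for i in idx],
            group_labels=self.group_labels[idx],
            mask=self.mask,
        )


def build_brain_mask(
    gm_maps: list[VoxelImage],
    wm_maps: list[VoxelImage],
    tissue_threshold: float = 0.1,
    rule: str = MASK_INTERSECTION,
) -> BrainMask:
    """Mask of voxels with GM or WM information, combined across subjects.

    Under the default intersection rule a voxel is kept iff GM+WM probability
    exceeds ``tissue_threshold`` for every subject; under ``union``, for any.
    """
    if not 0.0 <= tissue_threshold < 1.0:
        raise ValueError(f"tissue_threshold must lie in [0, 1), got {tissue_threshold}")
    if len(gm_maps) != len(wm_maps) or not gm_maps:
        raise ValueError("need equal, non-empty lists of GM and WM maps")
    shape = gm_maps[0].shape
    for i, (g, w) in enumerate(zip(gm_maps, wm_maps)):
        if g.shape != shape or w.shape != shape:
            raise ValueError(
                f"subject {i}: tissue-map grid {g.shape}/{w.shape} does not match {shape}"
            )
    if rule not in (MASK_INTERSECTION, MASK_UNION):
        raise ValueError(f"unknown mask rule {rule!r}")
    per_subject = np.stack([g.data + w.data > tissue_threshold for g, w in zip(gm_maps, wm_maps)])
    combined = per_subject.all(axis=0) if rule == MASK_INTERSECTION else per_subject.any(axis=0)
    if not combined.any():
        raise ValueError(
            f"empty brain mask (threshold {tissue_threshold}, rule {rule}): no voxel has "
            "tissue probability above threshold across subjects"
        )
    return BrainMask(mask=combined, provenance=f"gm+wm>{tissue_threshold}, {rule} across subjects")


def global_normalise(image: VoxelImage, mask: BrainMask) -> VoxelImage:
    """Divide an image by its in-mask mean; out-of-mask voxels pass through."""
    values = mask.flatten(image)
    mean = float(values.mean())
    if mean <= 0:
        raise ValueError(
            f"in-mask mean is {mean:.6g} (must be > 0); wrong modality or corrupted data"
        )
    out = image.data.copy()
    flat = out.ravel(order="C")
    flat[mask.indices] = values / mean
    return VoxelImage(out, affine=image.affine)


def prepare_modality(
    images: list[VoxelImage],
    mask: BrainMask,
    normalisation: str = NORM_NONE,
    log_transform: bool = False,
) -> np.ndarray:
    """Normalise each image and flatten in-mask voxels to a subjects × voxels matrix."""
    if normalisation not in (NORM_GLOBAL_MEAN, NORM_NONE):
        raise ValueError(f"unknown normalisation {normalisation!r}")
    check_common_grid(images)
    rows = []
    for i, image in enumerate(images):
        values = mask.flatten(image)
        if normalisation == NORM_GLOBAL_MEAN:
            mean = float(values.mean())
            if mean <= 0:
                raise ValueError(f"subject {i}: in-mask mean {mean:.6g} is not positive")
            values = values / mean
        if log_transform:
            bad = int(np.count_nonzero(values <= 0))
            if bad:
                raise ValueError(
                    f"subject {i}: {bad} non-positive in-mask voxels; log transform undefined"
                )
            values = np.log(values)
        rows.append(values)
    return np.vstack(rows)


def build_data_matrix(
    cohort: Cohort,
    modality: str,
    mask: BrainMask,
    normalisation: str = NORM_NONE,
    log_transform: bool = False,
) -> DataMatrix:
    """Prepare one modality of a cohort as a :class:`DataMatrix`."""
    images = [s.images[modality] for s in cohort.subjects]
    matrix = prepare_modality(images, mask, normalisation, log_transform)
    return DataMatrix(
        matrix=matrix,
        subject_ids=[s.subject_id for s in cohort.subjects],
        group_labels=np.asarray([s.group for s in cohort.subjects], dtype=object),
        mask=mask,
    )
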