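"""Grand mean profile, residual profiles, and the PCA decomposition with VAF.

The decomposition runs in subject space: eigendecompose the n × n Gram matrix
of the residual profiles and map eigenvectors back to voxel space, so cost
scales with subject count rather than voxel count. The residual matrix is not
re-centred before decomposition — the grand mean profile (GMP) subtraction is
the centring step of the model — so the returned components span the full
residual row space (numerical rank ≤ n) and, with every component retained,
scores × componentsᵀ reconstructs the residual matrix exactly.

Per-component VAF (variance accounted for) is the eigenvalue share of the
total squared residual norm, in percent; it sums to 100 over all returned
components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .io_formats import GROUP_REFERENCE, GROUP_TARGET
from .preprocess import DataMatrix

RESIDUAL_ALL = "all"
RESIDUAL_TARGET_ONLY = "target_only"

GMP_REFERENCE_ONLY = "reference_only"
GMP_POOLED = "pooled"

SELECT_CUMULATIVE = "cumulative"
SELECT_PER_COMPONENT = "per_component"

_RANK_RTOL = 1e-10


@dataclass
class GMPProfile:
    """Voxel-wise mean image of the reference group (the model's centring profile)."""

    profile: np.ndarray
    n_reference: int

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=np.float64).ravel()
        if self.n_reference < 1:
            raise ValueError("GMP requires at least one reference subject")


@dataclass
class ResidualProfileMatrix:
    """Subjects × in-mask voxels after GMP subtraction; rows carry group labels."""

    matrix: np.ndarray
    subject_ids: list[str]
    group_labels: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.group_labels = np.asarray(self.group_labels, dtype=object)
        if self.matrix.shape[0] != len(self.subject_ids) or self.matrix.shape[0] != len(
            self.group_labels
        ):
            raise ValueError("row bookkeeping does not match matrix row count")


@dataclass
class PCAResult:
    """Voxel-space components (rows, unit norm), subject scores, per-component VAF (%)."""

    components: np.ndarray
    subject_scores: np.ndarray
    vaf: np.ndarray

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=np.float64)
        self.subject_scores = np.asarray(self.subject_scores, dtype=np.float64)
        self.vaf = np.asarray(self.vaf, dtype=np.float64)

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def compute_gmp(reference_rows: np.ndarray) -> GMPProfile:
    """Column-wise mean over reference-group rows only."""
    rows = np.atleast_2d(np.asarray(reference_rows, dtype=np.float64))
    if rows.shape[0] < 1 or rows.size == 0:
        raise ValueError("compute_gmp needs at least one reference row")
    return GMPProfile(profile=rows.mean(axis=0), n_reference=rows.shape[0])


def residual_profiles(
    data: DataMatrix,
    gmp: GMPProfile,
    scope: str = RESIDUAL_ALL,
) -> ResidualProfileMatrix:
    """Subtract the GMP from each subject row (both groups by default)."""
    if data.matrix.shape[1] != gmp.profile.shape[0]:
        raise ValueError(
            f"voxel-count mismatch: matrix has {data.matrix.shape[1]} columns, "
            f"GMP has {gmp.profile.shape[0]}"
        )
    if scope == RESIDUAL_ALL:
        keep = np.ones(data.n_subjects, dtype=bool)
    elif scope == RESIDUAL_TARGET_ONLY:
        keep = data.group_labels == GROUP_TARGET
    else:
        raise ValueError(f"unknown residual scope {scope!r}")
    return ResidualProfileMatrix(
        matrix=data.matrix[keep] - gmp.profile,
        subject_ids=[s for s, k in zip(data.subject_ids, keep) if k],
        group_labels=data.group_labels[keep],
    )


def run_pca(residuals: ResidualProfileMatrix) -> PCAResult:
    """Subject-space PCA of the residual profiles.

    Components are unit-norm voxel vectors ordered by decreasing VAF, each
    sign-oriented so the target group's mean score is >= the reference group's
    (higher score = more target-like); on a tie the first non-zero loading is
    made positive. Raises on an all-zero residual matrix.
    """
    R = residuals.matrix
    n, p = R.shape
    if n < 2 or p < 2:
        raise ValueError(f"PCA needs >= 2 subjects and >= 2 voxels, got {n} x {p}")
    total = float(np.sum(R * R))
    if total == 0.0:
        raise ValueError("all-zero residual matrix: no variance to decompose")

    gram = R @ R.T
    eigval, eigvec = scipy.linalg.eigh(gram)  # ascending
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    keep = eigval > eigval[0] * _RANK_RTOL
    eigval = eigval[keep]
    eigvec = eigvec[:, keep]

    # Map subject-space eigenvectors to unit-norm voxel-space components.
    components = (R.T @ eigvec) / np.sqrt(eigval)
    components = components.T  # k x p
    scores = R @ components.T  # n x k

    is_target = residuals.group_labels == GROUP_TARGET
    is_reference = residuals.group_labels == GROUP_REFERENCE
    for k in range(components.shape[0]):
        if is_target.any() and is_reference.any():
            diff = scores[is_target, k].mean() - scores[is_reference, k].mean()
        else:
            diff = 0.0
        if diff < 0:
            components[k] *= -1.0
            scores[:, k] *= -1.0
        elif diff == 0:
            nz = np.flatnonzero(components[k])
            if nz.size and components[k, nz[0]] < 0:
                components[k] *= -1.0
                scores[:, k] *= -1.0

    vaf = 100.0 * eigval / total
    return PCAResult(components=components, subject_scores=scores, vaf=vaf)


def select_components(
    pca: PCAResult,
    vaf_threshold: float = 50.0,
    rule: str = SELECT_CUMULATIVE,
) -> list[int]:
    """Retain components explaining at least ``vaf_threshold`` percent of variance.

    Default reading: the smallest prefix (in VAF order) whose *cumulative* VAF
    reaches the threshold. The stricter per-component reading (each retained PC
    alone >= threshold) is available as ``rule='per_component'``.
    """
    if not 0 < vaf_threshold <= 100:
        raise ValueError(f"vaf_threshold must lie in (0, 100], got {vaf_threshold}")
    if rule == SELECT_CUMULATIVE:
        cum = np.cumsum(pca.vaf)
        # float tolerance keeps thresholds like 100 reachable
        k = int(np.searchsorted(cum, vaf_threshold - 1e-9) + 1)
        k = min(k, pca.n_components)
        return list(range(k))
    if rule == SELECT_PER_COMPONENT:
        return [i for i, v in enumerate(pca.vaf) if v >= vaf_threshold]
    raise ValueError(f"unknown selection rule {rule!r}")
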