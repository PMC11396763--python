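"""Multimodal brain-phantom cohorts with a known embedded differentiating pattern.

The phantom emulates the data structure the covariance-pattern analysis expects:
two groups of pre-aligned 3-D volumes sharing one anatomy (an ellipsoidal
white-matter core inside a grey-matter shell), where each target-group subject
deviates from the reference mean along one shared spatial pattern.

The true pattern is a sum of signed Gaussian blobs with peak amplitude ~1,
applied to subject images as ``loading × pattern_raw`` with
``loading ~ Normal(effect_amplitude, loading_sd)`` for target subjects and
``Normal(0, loading_sd)`` for reference subjects. ``effect_amplitude`` is
therefore a per-voxel contrast in the blob cores, directly comparable to
``noise_sd``. The *stored* ground-truth pattern is the unit-norm version of
the raw pattern, so cosine similarities against it are scale-free.

Lesions are small hyper-/hypo-intense spheres at random white-matter
locations, drawn identically for both groups: structured nuisance that is
uncorrelated with phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    GROUP_REFERENCE,
    GROUP_TARGET,
    Cohort,
    Subject,
    VoxelImage,
)

GLOBALLY_SCALED = "globally_scaled"
INTRINSICALLY_NORMALISED = "intrinsically_normalised"
MODALITY_KINDS = (GLOBALLY_SCALED, INTRINSICALLY_NORMALISED)

# Fixed baseline tissue intensities: deterministic values keep analytic checks easy.
WM_INTENSITY = 1.0
GM_INTENSITY = 0.7
BACKGROUND_INTENSITY = 0.0

LESION_AMPLITUDE = 0.3


@dataclass
class PhantomConfig:
    """Study-condition parameters for one synthetic cohort.

    Defaults encode the reference study design: a 32³ grid, 15+15 training-size
    groups (use 30/20 for a full cohort with validation remainder), target-group
    pattern expression five times the voxel noise, and moderate subject-level
    loading variability.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    n_reference: int = 15
    n_target: int = 15
    effect_amplitude: float = 1.0
    loading_sd: float = 0.3
    noise_sd: float = 0.2
    n_blobs: int = 6
    modalities: dict[str, str] = field(
        default_factory=lambda: {"qmap": INTRINSICALLY_NORMALISED}
    )
    global_scale_sd: float = 0.1
    lesion_count_range: tuple[int, int] = (0, 5)
    modality_loading_rho: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_reference < 0 or self.n_target < 0:
            raise ValueError("subject counts must be >= 0")
        if any(g < 8 for g in self.grid_shape) or len(self.grid_shape) != 3:
            raise ValueError(f"grid_shape must be a triple with each axis >= 8, got {self.grid_shape}")
        if self.noise_sd < 0 or self.loading_sd < 0 or self.global_scale_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_blobs < 1:
            raise ValueError("n_blobs must be >= 1")
        for name, kind in self.modalities.items():
            if kind not in MODALITY_KINDS:
                raise ValueError(f"modality {name!r}: unknown kind {kind!r}")
        lo, hi = self.lesion_count_range
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid lesion_count_range {self.lesion_count_range}")
        if not 0.0 <= self.modality_loading_rho <= 1.0:
            raise ValueError("modality_loading_rho must lie in [0, 1]")


@dataclass
class PhantomCohort(Cohort):
    """Cohort plus ground truth: the embedded pattern and per-subject loadings."""

    truth_pattern: VoxelImage | None = None
    true_loadings: dict[str, np.ndarray] | None = None
    config: PhantomConfig | None = None


def _ellipsoid_mask(shape: tuple[int, int, int], semiaxes: np.ndarray) -> np.ndarray:
    centre = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    d2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centre, semiaxes))
    return d2 <= 1.0


def brain_geometry(grid_shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Return (brain, wm, gm, semiaxes_outer) boolean/float fields for the phantom anatomy.

    The brain is an outer ellipsoid (semi-axes 0.45 × axis length); the inner
    0.28 × ellipsoid is white matter, the surrounding shell grey matter.
    """
    shape = tuple(int(g) for g in grid_shape)
    outer_axes = 0.45 * np.asarray(shape, dtype=float)
    inner_axes = 0.28 * np.asarray(shape, dtype=float)
    outer = _ellipsoid_mask(shape, outer_axes)
    inner = _ellipsoid_mask(shape, inner_axes)
    if not outer.any():
        raise ValueError(f"degenerate ellipsoid: empty brain support for grid {shape}")
    wm = inner
    gm = outer & ~inner
    return outer, wm, gm, outer_axes


def _make_truth_pattern(
    rng: np.random.Generator,
    brain: np.ndarray,
    n_blobs: int,
    shape: tuple[int, int, int],
) -> np.ndarray:
    """Sum of signed 3-D Gaussian blobs centred inside the brain, restricted to it."""
    coords = np.argwhere(brain)
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    pattern = np.zeros(shape, dtype=np.float64)
    for _ in range(n_blobs):
        centre = coords[rng.integers(0, len(coords))]
        # lobe/nucleus-scale structures: ~1/8 of the brain's linear extent
        sigma = rng.uniform(2.0, 4.0) * (min(shape) / 32.0)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        d2 = sum((g - c) ** 2 for g, c in zip(grids, centre))
        pattern += sign * np.exp(-d2 / (2.0 * sigma**2))
    pattern[~brain] = 0.0
    return pattern


def generate_cohort(config: PhantomConfig) -> PhantomCohort:
    """Generate a phantom cohort with known truth; bit-identical under a fixed seed."""
    config.validate()
    shape = tuple(int(g) for g in config.grid_shape)
    brain, wm, gm, _ = brain_geometry(shape)

    root = np.random.SeedSequence(config.seed)
    pattern_ss, subjects_ss = root.spawn(2)
    pattern_rng = np.random.default_rng(pattern_ss)

    raw_pattern = _make_truth_pattern(pattern_rng, brain, config.n_blobs, shape)
    norm = float(np.linalg.norm(raw_pattern))
    if norm == 0.0:
        raise ValueError("degenerate truth pattern: all-zero on the brain support")
    truth = raw_pattern / norm

    baseline = np.full(shape, BACKGROUND_INTENSITY, dtype=np.float64)
    baseline[gm] = GM_INTENSITY
    baseline[wm] = WM_INTENSITY
    wm_coords = np.argwhere(wm)

    n_total = config.n_reference + config.n_target
    groups = [GROUP_REFERENCE] * config.n_reference + [GROUP_TARGET] * config.n_target
    subject_seeds = subjects_ss.spawn(n_total)

    modality_names = list(config.modalities)
    loadings: dict[str, list[float]] = {m: [] for m in modality_names}
    subjects: list[Subject] = []
    gm_img = VoxelImage(gm.astype(np.float64))
    wm_img = VoxelImage(wm.astype(np.float64))
    rho = config.modality_loading_rho

    for i, (group, ss) in enumerate(zip(groups, subject_seeds)):
        rng = np.random.default_rng(ss)
        mean_loading = config.effect_amplitude if group == GROUP_TARGET else 0.0
        shared = rng.normal(0.0, 1.0)

        # Lesions are shared across modalities: one anatomical event per subject.
        lesion_field = np.zeros(shape, dtype=np.float64)
        lo, hi = config.lesion_count_range
        n_lesions = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
        for _ in range(n_lesions):
            centre = wm_coords[rng.integers(0, len(wm_coords))]
            radius = rng.uniform(1.0, 2.0)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            lo_corner = np.maximum(centre - 3, 0)
            hi_corner = np.minimum(centre + 4, shape)
            sl = tuple(slice(a, b) for a, b in zip(lo_corner, hi_corner))
            local = np.meshgrid(
                *[np.arange(a, b, dtype=float) for a, b in zip(lo_corner, hi_corner)],
                indexing="ij",
            )
            d2 = sum((g - c) ** 2 for g, c in zip(local, centre))
            lesion_field[sl] += np.where(d2 <= radius**2, sign * LESION_AMPLITUDE, 0.0)
        lesion_field[~wm] = 0.0

        images: dict[str, VoxelImage] = {}
        for modality in modality_names:
            indep = rng.normal(0.0, 1.0)
            unit = rho * shared + np.sqrt(max(0.0, 1.0 - rho**2)) * indep
            loading = mean_loading + config.loading_sd * unit
            loadings[modality].append(loading)
            data = baseline + loading * raw_pattern + lesion_field
            if config.noise_sd > 0:
                data = data + rng.normal(0.0, config.noise_sd, size=shape)
            if config.modalities[modality] == GLOBALLY_SCALED:
                data = data * rng.normal(1.0, config.global_scale_sd)
            images[modality] = VoxelImage(data)

        subjects.append(
            Subject(
                subject_id=f"sub-{i:03d}",
                group=group,
                images=images,
                gm=gm_img,
                wm=wm_img,
            )
        )

    return PhantomCohort(
        subjects=subjects,
        truth_pattern=VoxelImage(truth),
        true_loadings={m: np.asarray(v) for m, v in loadings.items()},
        config=config,
    )
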