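"""Bootstrap stability, leave-one-out cross-validation, and the held-out group test.

Bootstrap resamples subjects with replacement *within* each group, preserving
the per-group design, and re-derives the pattern from scratch each time; a
repetition succeeds when the derivation completes with a non-empty selection
and the in-resample scores separate the groups (one-sided rank-sum p < alpha).

LOOCV re-derives the full pipeline with each subject held out — the held-out
subject never touches the GMP, the PCA, the stepwise selection, or the
pattern — and scores that subject with the fold's model. The cross-validated
score set sustains validation when the target group's scores rank
significantly above the reference group's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu

from .io_formats import GROUP_REFERENCE, GROUP_TARGET
from .pattern_model import DerivationSettings, derive_pattern, project_score
from .preprocess import DataMatrix


@dataclass
class BootstrapRepetition:
    success: bool
    pattern_cosine: float | None = None


@dataclass
class BootstrapReport:
    n_repetitions: int
    success_percent: float
    per_repetition: list[BootstrapRepetition] = field(default_factory=list)


@dataclass
class LoocvReport:
    cv_scores: np.ndarray  # one held-out z-score per training subject
    group_labels: np.ndarray
    subject_ids: list[str]
    p_value: float
    sustained: bool
    degraded: bool = False  # some fold had an empty selection (scored 0)


def _ranksum_greater(target_scores: np.ndarray, reference_scores: np.ndarray) -> float:
    """One-sided Mann-Whitney p for target > reference; 1.0 on fully tied input."""
    pooled = np.concatenate([target_scores, reference_scores])
    if np.all(pooled == pooled[0]):
        return 1.0
    method = "exact" if len(np.unique(pooled)) == len(pooled) else "asymptotic"
    return float(
        mannwhitneyu(target_scores, reference_scores, alternative="greater", method=method).pvalue
    )


def bootstrap_stability(
    data: DataMatrix,
    settings: DerivationSettings | None = None,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    original_pattern: np.ndarray | None = None,
) -> BootstrapReport:
    """Within-group bootstrap of the whole derivation; reports the success rate.

    When ``original_pattern`` is given, each successful repetition also records
    the cosine of its pattern with the original.
    """
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    labels = data.group_labels
    ref_idx = np.flatnonzero(labels == GROUP_REFERENCE)
    tgt_idx = np.flatnonzero(labels == GROUP_TARGET)
    if len(ref_idx) < 2 or len(tgt_idx) < 2:
        raise ValueError("bootstrap needs >= 2 subjects per group")
    rng = np.random.default_rng(seed)
    settings = settings or DerivationSettings()

    reps: list[BootstrapRepetition] = []
    for _ in range(B):
        idx = np.concatenate(
            [
                rng.choice(ref_idx, size=len(ref_idx), replace=True),
                rng.choice(tgt_idx, size=len(tgt_idx), replace=True),
            ]
        )
        resample = data.subset(idx)
        try:
            model = derive_pattern(resample, settings)
        except ValueError:
            model = None  # degenerate resample counts as failure, never raises
        if model is None:
            reps.append(BootstrapRepetition(success=False))
            continue
        scores = model.training_scores
        p = _ranksum_greater(
            scores[resample.group_labels == GROUP_TARGET],
            scores[resample.group_labels == GROUP_REFERENCE],
        )
        cosine = None
        if original_pattern is not None:
            denom = np.linalg.norm(model.pattern.pattern) * np.linalg.norm(original_pattern)
            cosine = float(model.pattern.pattern @ original_pattern / denom)
        reps.append(BootstrapRepetition(success=bool(p < alpha), pattern_cosine=cosine))

    n_success = sum(r.success for r in reps)
    return BootstrapReport(
        n_repetitions=B,
        success_percent=100.0 * n_success / B,
        per_repetition=reps,
    )


def loocv(
    data: DataMatrix,
    settings: DerivationSettings | None = None,
    alpha: float = 0.05,
) -> LoocvReport:
    """Leave-one-out cross-validation of the pattern derivation.

    Each fold re-derives GMP, PCA, selection and pattern on the n−1 remaining
    subjects and scores the held-out subject (z-scored against the fold's
    reference training scores, so folds share one scale). A fold whose
    selection is empty contributes a score of 0 and marks the report degraded.
    """
    labels = data.group_labels
    n_ref = int(np.sum(labels == GROUP_REFERENCE))
    n_tgt = int(np.sum(labels == GROUP_TARGET))
    if n_ref < 3 or n_tgt < 3:
        raise ValueError(f"LOOCV needs >= 3 subjects per group, got {n_ref}/{n_tgt}")
    settings = settings or DerivationSettings()

    n = data.n_subjects
    cv_scores = np.zeros(n)
    degraded = False
    for i in range(n):
        rest = data.subset(np.r_[0:i, i + 1 : n])
        assert rest.n_subjects == n - 1
        model = derive_pattern(rest, settings)
        if model is None:
            degraded = True
            continue
        _, z = project_score(data.matrix[i], model.gmp, model.pattern)
        cv_scores[i] = z if z is not None else 0.0

    p = _ranksum_greater(cv_scores[labels == GROUP_TARGET], cv_scores[labels == GROUP_REFERENCE])
    return LoocvReport(
        cv_scores=cv_scores,
        group_labels=labels,
        subject_ids=list(data.subject_ids),
        p_value=p,
        sustained=bool(p < alpha),
        degraded=degraded,
    )


def validation_group_test(
    validation_scores: np.ndarray,
    reference_training_scores: np.ndarray,
    alpha: float = 0.05,
) -> tuple[float, bool]:
    """One-sided rank-sum test: are held-out scores higher than the reference
    training group's? Returns (p_value, decision)."""
    v = np.asarray(validation_scores, dtype=np.float64)
    r = np.asarray(reference_training_scores, dtype=np.float64)
    if v.size == 0 or r.size == 0:
        raise ValueError("both score lists must be non-empty")
    p = _ranksum_greater(v, r)
    return p, bool(p < alpha)
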