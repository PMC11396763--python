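"""Combine retained principal components into the differentiating pattern.

Forward stepwise logistic regression picks the PC subset that best separates
the groups (AIC by default, likelihood-ratio entry as an alternative); the
selected components, weighted by their logistic coefficients, are summed and
unit-normalised into the final pattern. A subject's expression of the pattern
is the inner product of its GMP-subtracted residual profile with the pattern,
optionally z-scored against the reference training group.

Complete separation — common at n = 30 with a strong pattern — is detected
and flagged rather than silently returning divergent weights; a lightly
ridge-penalised Newton fit supplies finite coefficients in that case.
Downstream classification is unaffected because scores, not probabilities,
are thresholded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .io_formats import GROUP_REFERENCE, GROUP_TARGET
from .preprocess import DataMatrix
from .ssm_core import (
    GMP_POOLED,
    GMP_REFERENCE_ONLY,
    RESIDUAL_ALL,
    SELECT_CUMULATIVE,
    GMPProfile,
    PCAResult,
    compute_gmp,
    residual_profiles,
    run_pca,
    select_components,
)

CRITERION_AIC = "aic"
CRITERION_LRT = "lrt_p"

_SEPARATION_PROB_TOL = 1e-6
_RIDGE_LAMBDA = 1e-4


class EmptySelectionError(ValueError):
    """No principal component improved the selection criterion."""


@dataclass
class StepwiseResult:
    selected: list[int]
    coefficients: np.ndarray  # intercept first, then one weight per selected component
    separation_flag: bool


@dataclass
class DifferentiatingPattern:
    """The final unit-norm voxel pattern and its provenance."""

    pattern: np.ndarray
    selected_components: list[int]
    logistic_coefficients: np.ndarray
    total_vaf: float
    reference_score_mean: float | None = None
    reference_score_sd: float | None = None
    threshold: float | None = None
    separation_flag: bool = False

    def __post_init__(self) -> None:
        self.pattern = np.asarray(self.pattern, dtype=np.float64).ravel()


@dataclass
class DerivationSettings:
    """Tunable knobs of the pattern-derivation pipeline (defaults = study design)."""

    vaf_threshold: float = 50.0
    selection_rule: str = SELECT_CUMULATIVE
    criterion: str = CRITERION_AIC
    entry_alpha: float = 0.05
    gmp_scope: str = GMP_REFERENCE_ONLY
    residual_scope: str = RESIDUAL_ALL


@dataclass
class DerivedModel:
    """Everything needed to score a new subject: GMP, pattern, reference statistics."""

    gmp: GMPProfile
    pattern: DifferentiatingPattern
    pca: PCAResult
    retained: list[int]
    training_scores: np.ndarray = field(default_factory=lambda: np.empty(0))
    training_z: np.ndarray = field(default_factory=lambda: np.empty(0))


def _ridge_logit(X: np.ndarray, y: np.ndarray, lam: float = _RIDGE_LAMBDA, n_iter: int = 50) -> tuple[np.ndarray, float]:
    """Ridge-penalised logistic Newton fit; finite even under complete separation.

    Returns (coefficients, unpenalised log-likelihood). Intercept is column 0
    of ``X`` and is penalised like the rest — acceptable at the tiny lambda
    used, which exists only to bound divergent coefficients.
    """
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(n_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1.0 - mu) + 1e-12
        grad = X.T @ (y - mu) - lam * beta
        H = (X.T * W) @ X + lam * np.eye(k)
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = X @ beta
    llf = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    return beta, llf


def _fit_logit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Fit a logistic model; returns (params, llf, separated).

    Uses statsmodels' Logit; on complete separation or non-convergence, falls
    back to the ridge-Newton fit for finite last-iteration coefficients.
    """
    separated = False
    with warnings.catch_warnings():
        # overflow in the logistic link near separation is expected and benign
        warnings.filterwarnings("ignore", category=RuntimeWarning)
        warnings.filterwarnings("error", category=PerfectSeparationWarning)
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100, warn_convergence=False)
            params = np.asarray(res.params, dtype=np.float64)
            llf = float(res.llf)
            fitted = 1.0 / (1.0 + np.exp(-(X @ params)))
            if np.all(np.abs(fitted - y) < _SEPARATION_PROB_TOL):
                separated = True
            if not np.all(np.isfinite(params)):
                raise PerfectSeparationError("non-finite coefficients")
        except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
            separated = True
            params, llf = _ridge_logit(X, y)
    return params, llf, separated


def stepwise_logistic(
    subject_scores: np.ndarray,
    labels: np.ndarray,
    criterion: str = CRITERION_AIC,
    entry_alpha: float = 0.05,
) -> StepwiseResult:
    """Forward stepwise logistic selection over candidate component scores.

    Starts from the intercept-only model; at each step adds the candidate that
    most improves the criterion (largest AIC decrease, or smallest
    likelihood-ratio entry p below ``entry_alpha``); stops when none improves.
    If the step's model achieves complete separation its MLE does not exist:
    selection stops with the separation flag set and the last finite model is
    returned — unless no component model precedes it, in which case the
    perfectly discriminating candidate is kept with bounded ridge
    coefficients. An empty selection is a legal outcome (no differentiating
    pattern).
    """
    from scipy.stats import chi2

    scores = np.atleast_2d(np.asarray(subject_scores, dtype=np.float64))
    labels = np.asarray(labels)
    y = (labels == GROUP_TARGET).astype(np.float64)
    n, k = scores.shape
    if n != labels.shape[0]:
        raise ValueError("scores and labels disagree on subject count")
    n_target = int(y.sum())
    if n_target < 2 or n - n_target < 2:
        raise ValueError(
            f"need >= 2 subjects per group, got {n - n_target} reference / {n_target} target"
        )
    if criterion not in (CRITERION_AIC, CRITERION_LRT):
        raise ValueError(f"unknown criterion {criterion!r}")

    intercept = np.ones((n, 1))
    selected: list[int] = []
    params, llf, _ = _fit_logit(intercept, y)
    current_aic = 2 * 1 - 2 * llf
    current_llf = llf
    current_params = params
    separation = False

    while len(selected) < k:
        best = None
        for j in range(k):
            if j in selected:
                continue
            X = np.hstack([intercept, scores[:, selected + [j]]])
            cand_params, cand_llf, cand_sep = _fit_logit(X, y)
            n_par = X.shape[1]
            cand_aic = 2 * n_par - 2 * cand_llf
            lrt = 2 * (cand_llf - current_llf)
            p_entry = float(chi2.sf(max(lrt, 0.0), df=1))
            entry = (best is None) or (
                cand_aic < best[1] if criterion == CRITERION_AIC else p_entry < best[4]
            )
            if entry:
                best = (j, cand_aic, cand_params, cand_llf, p_entry, cand_sep)
        j, cand_aic, cand_params, cand_llf, p_entry, cand_sep = best
        improves = (
            cand_aic < current_aic - 1e-10
            if criterion == CRITERION_AIC
            else p_entry < entry_alpha
        )
        if not improves:
            break
        if cand_sep:
            # The separated model's MLE does not exist; stop and return the
            # last finite model. Only when no component model precedes it is
            # the separating candidate kept (with bounded ridge coefficients),
            # so a perfectly discriminating lone candidate is still selected.
            separation = True
            if not selected:
                selected.append(j)
                current_params = cand_params
            break
        selected.append(j)
        current_aic, current_llf, current_params = cand_aic, cand_llf, cand_params

    return StepwiseResult(
        selected=selected,
        coefficients=np.asarray(current_params, dtype=np.float64),
        separation_flag=separation,
    )


def combine_pattern(
    pca: PCAResult,
    selected: list[int],
    coefficients: np.ndarray,
    separation_flag: bool = False,
) -> DifferentiatingPattern:
    """Weighted sum of the selected components, unit-normalised.

    ``coefficients`` holds one weight per selected component (no intercept).
    Total VAF is the sum of the selected components' VAF.
    """
    if not selected:
        raise EmptySelectionError(
            "no components selected: no differentiating pattern; caller should "
            "report the modality as non-differentiating"
        )
    weights = np.asarray(coefficients, dtype=np.float64).ravel()
    if weights.shape[0] != len(selected):
        raise ValueError(f"{len(selected)} components selected but {weights.shape[0]} weights given")
    raw = weights @ pca.components[selected]
    norm = float(np.linalg.norm(raw))
    if norm == 0.0:
        raise ValueError("zero combined pattern (all weights zero?)")
    return DifferentiatingPattern(
        pattern=raw / norm,
        selected_components=list(selected),
        logistic_coefficients=weights,
        total_vaf=float(np.sum(pca.vaf[selected])),
        separation_flag=separation_flag,
    )


def fit_reference_statistics(
    pattern: DifferentiatingPattern,
    data: DataMatrix,
    gmp: GMPProfile,
) -> DifferentiatingPattern:
    """Set the z-scoring statistics from the reference training group's raw scores."""
    ref_rows = data.rows_for(GROUP_REFERENCE)
    if ref_rows.shape[0] < 2:
        raise ValueError("need >= 2 reference subjects to fit score statistics")
    raw = (ref_rows - gmp.profile) @ pattern.pattern
    pattern.reference_score_mean = float(raw.mean())
    sd = float(raw.std(ddof=1))
    pattern.reference_score_sd = sd if sd > 0 else None
    return pattern


def project_score(
    subject_row: np.ndarray,
    gmp: GMPProfile,
    pattern: DifferentiatingPattern,
) -> tuple[float, float | None]:
    """Project a subject onto the pattern: raw inner-product score and z-score.

    raw = (subject − GMP) · pattern; z standardises raw against the reference
    training group (None when those statistics are unset or degenerate).
    """
    row = np.asarray(subject_row, dtype=np.float64).ravel()
    if row.shape[0] != gmp.profile.shape[0] or row.shape[0] != pattern.pattern.shape[0]:
        raise ValueError("subject row, GMP and pattern lengths disagree")
    raw = float((row - gmp.profile) @ pattern.pattern)
    if pattern.reference_score_mean is None:
        return raw, None
    if pattern.reference_score_sd is None:
        return raw, None
    z = (raw - pattern.reference_score_mean) / pattern.reference_score_sd
    return raw, z


def derive_pattern(
    data: DataMatrix,
    settings: DerivationSettings | None = None,
) -> DerivedModel | None:
    """Run the full derivation on a training set: GMP → residuals → PCA →
    VAF retention → stepwise logistic → combined pattern → reference statistics.

    Returns None when stepwise selection is empty (no differentiating pattern).
    """
    settings = settings or DerivationSettings()
    if settings.gmp_scope == GMP_REFERENCE_ONLY:
        gmp = compute_gmp(data.rows_for(GROUP_REFERENCE))
    elif settings.gmp_scope == GMP_POOLED:
        gmp = compute_gmp(data.matrix)
    else:
        raise ValueError(f"unknown gmp_scope {settings.gmp_scope!r}")
    residuals = residual_profiles(data, gmp, scope=settings.residual_scope)
    pca = run_pca(residuals)
    retained = select_components(pca, settings.vaf_threshold, settings.selection_rule)
    step = stepwise_logistic(
        pca.subject_scores[:, retained],
        residuals.group_labels,
        criterion=settings.criterion,
        entry_alpha=settings.entry_alpha,
    )
    if not step.selected:
        return None
    selected_global = [retained[i] for i in step.selected]
    pattern = combine_pattern(
        pca, selected_global, step.coefficients[1:], separation_flag=step.separation_flag
    )
    fit_reference_statistics(pattern, data, gmp)
    raw_scores = (data.matrix - gmp.profile) @ pattern.pattern
    if pattern.reference_score_sd is not None:
        z_scores = (raw_scores - pattern.reference_score_mean) / pattern.reference_score_sd
    else:
        z_scores = np.full_like(raw_scores, np.nan)
    return DerivedModel(
        gmp=gmp,
        pattern=pattern,
        pca=pca,
        retained=retained,
        training_scores=raw_scores,
        training_z=z_scores,
    )
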