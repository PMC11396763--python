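"""End-to-end study orchestration.

Reproduces the experimental structure of the reference design on any cohort:
a stratified random training/validation split (e.g. 15+15 training from a
30/20 cohort, remainder to validation), an independent pattern derivation per
modality, bootstrap and LOOCV stability checks, ROC/Youden thresholding of the
cross-validated scores, scoring and classification of the held-out validation
subjects, and a two-modality concordance combination.

Validation subjects never contribute to the GMP, the PCA, the stepwise
selection, the bootstrap, or the threshold choice; the whole-brain mask is the
only quantity built from all subjects' tissue maps, since it encodes shared
anatomy rather than group contrast.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import GROUP_REFERENCE, GROUP_TARGET, Cohort
from .pattern_model import DerivationSettings, DerivedModel, derive_pattern, project_score
from .preprocess import (
    MASK_INTERSECTION,
    NORM_GLOBAL_MEAN,
    NORM_NONE,
    BrainMask,
    DataMatrix,
    build_brain_mask,
    build_data_matrix,
)
from .roc_metrics import RocReport, classify, concordance_combine, roc_report
from .synthetic_cohort import GLOBALLY_SCALED, PhantomCohort
from .validation import BootstrapReport, LoocvReport, bootstrap_stability, loocv, validation_group_test

REPORT_SCHEMA_VERSION = "1"


@dataclass
class StudyConfig:
    """Study design parameters; defaults mirror the reference 15/15 design."""

    modalities: list[str] | None = None  # None: every modality in the cohort
    n_reference_train: int = 15
    n_target_train: int = 15
    vaf_threshold: float = 50.0
    criterion: str = "aic"
    alpha: float = 0.05
    bootstrap_B: int = 1000
    seed: int = 0
    tissue_threshold: float = 0.1
    mask_rule: str = MASK_INTERSECTION
    normalisation: dict[str, str] = field(default_factory=dict)  # modality -> rule
    concordance_pair: tuple[str, str] | None = None  # None: two highest-AUC modalities

    def settings(self) -> DerivationSettings:
        return DerivationSettings(
            vaf_threshold=self.vaf_threshold,
            criterion=self.criterion,
            entry_alpha=self.alpha,
        )

    def validate(self) -> None:
        if self.n_reference_train < 3 or self.n_target_train < 3:
            raise ValueError("training counts must be >= 3 per group")
        if not 0 < self.vaf_threshold <= 100:
            raise ValueError("vaf_threshold must lie in (0, 100]")


@dataclass
class ModalityResult:
    modality: str
    model: DerivedModel | None
    bootstrap: BootstrapReport | None
    loocv_report: LoocvReport | None
    roc: RocReport | None
    validation_z: dict[str, float]
    validation_calls: dict[str, str]
    validation_p: float | None
    validation_decision: bool | None
    training_calls: dict[str, str]
    pattern_truth_cosine: float | None = None


@dataclass
class StudyResult:
    config: StudyConfig
    mask: BrainMask
    training_ids: list[str]
    validation_ids: list[str]
    modalities: dict[str, ModalityResult]
    concordance_pair: tuple[str, str] | None
    concordance: object | None

    def report(self) -> dict:
        """Machine-readable study report (stable schema, JSON-serialisable)."""
        out: dict = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "seed": self.config.seed,
            "n_mask_voxels": self.mask.n_voxels,
            "training_ids": list(self.training_ids),
            "validation_ids": list(self.validation_ids),
            "modalities": {},
        }
        for name, m in self.modalities.items():
            entry: dict = {"pattern_derived": m.model is not None}
            if m.model is not None:
                entry.update(
                    {
                        "selected_components": m.model.pattern.selected_components,
                        "total_vaf": round(m.model.pattern.total_vaf, 6),
                        "separation_flag": m.model.pattern.separation_flag,
                    }
                )
            if m.bootstrap is not None:
                entry["bootstrap"] = {
                    "n_repetitions": m.bootstrap.n_repetitions,
                    "success_percent": round(m.bootstrap.success_percent, 6),
                }
            if m.loocv_report is not None:
                entry["loocv"] = {
                    "sustained": m.loocv_report.sustained,
                    "p_value": round(m.loocv_report.p_value, 10),
                    "degraded": m.loocv_report.degraded,
                }
            if m.roc is not None:
                entry["roc"] = {
                    "auc": round(m.roc.auc, 10),
                    "youden_threshold": round(m.roc.youden_threshold, 10),
                    "sensitivity": round(m.roc.sensitivity, 6),
                    "specificity": round(m.roc.specificity, 6),
                    "ppv": m.roc.ppv,
                    "npv": m.roc.npv,
                    "confusion": list(m.roc.confusion),
                }
            if m.validation_p is not None:
                entry["validation"] = {
                    "p_value": round(m.validation_p, 10),
                    "decision": m.validation_decision,
                    "calls": dict(sorted(m.validation_calls.items())),
                }
            if m.pattern_truth_cosine is not None:
                entry["pattern_truth_cosine"] = round(m.pattern_truth_cosine, 10)
            out["modalities"][name] = entry
        if self.concordance is not None:
            c = self.concordance
            out["concordance"] = {
                "pair": list(self.concordance_pair),
                "concordance_percent": round(c.concordance_percent, 6),
                "sensitivity": c.sensitivity,
                "specificity": c.specificity,
                "ppv": c.ppv,
                "npv": c.npv,
                "confusion": list(c.confusion) if c.confusion else None,
            }
        return out

    def write_report(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.report(), indent=2, sort_keys=True) + "\n")
        return path


def split_cohort(
    cohort: Cohort, config: StudyConfig, seed: int | None = None
) -> tuple[list[str], list[str]]:
    """Uniform stratified random split into training and validation subject ids."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5B11]))
    training: list[str] = []
    for group, n_train in (
        (GROUP_REFERENCE, config.n_reference_train),
        (GROUP_TARGET, config.n_target_train),
    ):
        ids = cohort.ids(group)
        if len(ids) < n_train:
            raise ValueError(
                f"cannot draw {n_train} training subjects from {len(ids)} in group {group!r}"
            )
        chosen = rng.choice(len(ids), size=n_train, replace=False)
        training.extend(ids[i] for i in sorted(chosen))
    training_set = set(training)
    validation = [sid for sid in cohort.ids() if sid not in training_set]
    return training, validation


def _auto_normalisation(cohort: Cohort, config: StudyConfig, modality: str) -> str:
    if modality in config.normalisation:
        return config.normalisation[modality]
    kinds = getattr(getattr(cohort, "config", None), "modalities", None)
    if kinds and kinds.get(modality) == GLOBALLY_SCALED:
        return NORM_GLOBAL_MEAN
    return NORM_NONE


def run_study(cohort: Cohort, config: StudyConfig) -> StudyResult:
    """Execute the full design on a cohort; see module docstring for the stages."""
    config.validate()
    modalities = config.modalities or cohort.modalities
    mask = build_brain_mask(
        [s.gm for s in cohort.subjects],
        [s.wm for s in cohort.subjects],
        tissue_threshold=config.tissue_threshold,
        rule=config.mask_rule,
    )
    training_ids, validation_ids = split_cohort(cohort, config)
    settings = config.settings()

    truth = None
    if isinstance(cohort, PhantomCohort) and cohort.truth_pattern is not None:
        truth = mask.flatten(cohort.truth_pattern)
        truth = truth / np.linalg.norm(truth)

    results: dict[str, ModalityResult] = {}
    for modality in modalities:
        norm = _auto_normalisation(cohort, config, modality)
        full = build_data_matrix(cohort, modality, mask, normalisation=norm)
        train_rows = np.array([full.subject_ids.index(sid) for sid in training_ids])
        training = full.subset(train_rows)

        model = derive_pattern(training, settings)
        boot = bootstrap_stability(
            training,
            settings,
            B=config.bootstrap_B,
            seed=config.seed,
            alpha=config.alpha,
            original_pattern=model.pattern.pattern if model else None,
        )
        cv = loocv(training, settings, alpha=config.alpha)
        roc = roc_report(cv.cv_scores, cv.group_labels)

        validation_z: dict[str, float] = {}
        validation_calls: dict[str, str] = {}
        training_calls: dict[str, str] = {}
        validation_p = None
        validation_decision = None
        cosine = None
        if model is not None:
            val_rows = np.array([full.subject_ids.index(sid) for sid in validation_ids])
            for i in val_rows:
                _, z = project_score(full.matrix[i], model.gmp, model.pattern)
                validation_z[full.subject_ids[i]] = float(z) if z is not None else float("nan")
            ref_train_z = model.training_z[training.group_labels == GROUP_REFERENCE]
            if validation_z:
                validation_p, validation_decision = validation_group_test(
                    np.array(list(validation_z.values())), ref_train_z, alpha=config.alpha
                )
                calls = classify(
                    np.array(list(validation_z.values())), roc.youden_threshold
                )
                validation_calls = dict(zip(validation_z.keys(), calls.tolist()))
            train_calls = classify(cv.cv_scores, roc.youden_threshold)
            training_calls = dict(zip(cv.subject_ids, train_calls.tolist()))
            if truth is not None:
                cosine = float(model.pattern.pattern @ truth)

        results[modality] = ModalityResult(
            modality=modality,
            model=model,
            bootstrap=boot,
            loocv_report=cv,
            roc=roc,
            validation_z=validation_z,
            validation_calls=validation_calls,
            validation_p=validation_p,
            validation_decision=validation_decision,
            training_calls=training_calls,
            pattern_truth_cosine=cosine,
        )

    pair = config.concordance_pair
    concordance = None
    if pair is None and len(modalities) >= 2:
        derivable = [m for m in modalities if results[m].model is not None]
        derivable.sort(key=lambda m: results[m].roc.auc, reverse=True)
        if len(derivable) >= 2:
            pair = (derivable[0], derivable[1])
    if pair is not None:
        a, b = pair
        ra, rb = results[a], results[b]
        if ra.model is not None and rb.model is not None:
            ids = [sid for sid in ra.training_calls if sid in rb.training_calls]
            ids += [sid for sid in ra.validation_calls if sid in rb.validation_calls]
            calls_a = [
                ra.training_calls.get(sid, ra.validation_calls.get(sid)) for sid in ids
            ]
            calls_b = [
                rb.training_calls.get(sid, rb.validation_calls.get(sid)) for sid in ids
            ]
            truth_labels = {s.subject_id: s.group for s in cohort.subjects}
            concordance = concordance_combine(
                np.array(calls_a, dtype=object),
                np.array(calls_b, dtype=object),
                np.array([truth_labels[sid] for sid in ids], dtype=object),
            )

    return StudyResult(
        config=config,
        mask=mask,
        training_ids=training_ids,
        validation_ids=validation_ids,
        modalities=results,
        concordance_pair=pair,
        concordance=concordance,
    )
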