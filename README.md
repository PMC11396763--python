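# ssmpca

Scaled subprofile modelling with principal component analysis (SSM/PCA) for
voxel-wise phenotype differentiation from co-registered 3-D images.

SSM/PCA is a covariance-pattern technique: rather than testing each voxel
separately, it derives a single spatial pattern whose per-subject *expression
score* discriminates a target phenotype from a reference phenotype. It is the
framework behind disease-related pattern analyses in neurodegenerative
imaging (e.g. Parkinsonian syndromes with PET), applied here to structural
and magnetisation-transfer MRI contrasts of, for example, multiple sclerosis
phenotypes. This package is for imaging researchers who want the full
derive–validate–classify workflow as a tested, seedable pipeline, including a
synthetic brain-phantom generator with a known embedded pattern so every
stage can be exercised without clinical data.

## Model

Given spatially aligned images for a reference group and a target group:

1. **Mask** — keep voxels carrying grey- or white-matter information
   (GM + WM probability above threshold) for every subject.
2. **Normalise** — divide globally scaled contrasts (T1w/T2w/FLAIR-like) by
   their in-mask mean; intrinsically normalised quantitative maps
   (MTR/qMT-like) are used as-is.
3. **Grand mean profile (GMP)** — the voxel-wise mean image of the reference
   group, `g = mean_{i ∈ ref}(x_i)`.
4. **Residual profiles** — `r_i = x_i − g` for every subject, giving the
   subjects × voxels matrix `R`.
5. **PCA** — decompose `R` via the subject-space Gram matrix `R Rᵀ`; each
   component `c_k` is a unit-norm voxel image with *variance accounted for*
   `VAF_k = 100 · λ_k / Σλ`. The smallest set of leading components with
   cumulative VAF ≥ 50 % is retained.
6. **Pattern** — forward stepwise logistic regression on the component
   scores picks the subset best separating the groups; the differentiating
   pattern is `p = Σ β_k c_k / ‖Σ β_k c_k‖`.
7. **Score** — a subject's expression is `s = (x − g) · p`, z-scored against
   the reference training group; higher = more target-like.
8. **Validation** — within-group bootstrap of the whole derivation and
   leave-one-out cross-validation (LOOCV); the cross-validated scores feed a
   ROC analysis whose Youden-J-optimal threshold classifies subjects, with
   sensitivity, specificity, PPV and NPV reported.
9. **Concordance** — two modalities can be combined by keeping only subjects
   on whose phenotype both modality-specific classifiers agree.

## Worked example

```python
from ssmpca import PhantomConfig, StudyConfig, generate_cohort, run_study

cohort = generate_cohort(PhantomConfig(
    n_reference=30, n_target=20, seed=7,
    modalities={"qmap": "intrinsically_normalised", "t1w": "globally_scaled"},
))
result = run_study(cohort, StudyConfig(seed=7, bootstrap_B=200))
m = result.modalities["qmap"]
print(f"LOOCV AUC {m.roc.auc:.2f}, sensitivity {m.roc.sensitivity:.0f}%, "
      f"specificity {m.roc.specificity:.0f}%")
print(f"bootstrap success {m.bootstrap.success_percent:.1f}%, "
      f"LOOCV sustained: {m.loocv_report.sustained}")
print(f"pattern-truth cosine {m.pattern_truth_cosine:.2f}")
print(f"two-modality concordance {result.concordance.concordance_percent:.0f}%, "
      f"PPV in concordant subset {result.concordance.ppv}%")
```

prints

```
LOOCV AUC 1.00, sensitivity 100%, specificity 100%
bootstrap success 100.0%, LOOCV sustained: True
pattern-truth cosine 0.97
two-modality concordance 100%, PPV in concordant subset 87%
```

The phantom embeds a known spatial pattern expressed five times above the
voxel noise in target subjects, so the training design (15 + 15 subjects,
drawn from the 30/20 cohort; the remainder forms a held-out validation set)
recovers it almost perfectly: the derived pattern's cosine with the embedded
truth is 0.97, the cross-validated scores separate the groups completely,
and the two modalities — which share the same underlying pattern — agree on
every subject. `result.report()` returns the full machine-readable study
report; the same pipeline runs from the shell via
`ssmpca simulate-and-run --config study.yaml --out results/`.

## Layout

- `src/ssmpca/synthetic_cohort.py` — phantom cohorts with known ground truth
- `src/ssmpca/preprocess.py` — brain mask, normalisation, data matrices
- `src/ssmpca/ssm_core.py` — GMP, residual profiles, subject-space PCA, VAF
- `src/ssmpca/pattern_model.py` — stepwise logistic combination, scoring
- `src/ssmpca/validation.py` — bootstrap, LOOCV, held-out group test
- `src/ssmpca/roc_metrics.py` — ROC/AUC, Youden threshold, concordance
- `src/ssmpca/pipeline_driver.py` — study orchestration and reporting
- `src/ssmpca/io_formats.py` — NIfTI volumes, cohort manifests
- `docs/methods.md` — modelling assumptions and design choices
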