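# Methods

## The model

SSM/PCA treats the between-subject covariance of voxel intensities as the
object of interest. After masking and normalisation, each subject is a row
vector over in-mask voxels. The grand mean profile (GMP) — the voxel-wise
mean of the *reference* group — is subtracted from every subject, and PCA of
the resulting residual-profile matrix yields spatial components; a logistic
combination of the leading components forms a single differentiating
pattern. A subject's pattern-expression score is the inner product of its
residual profile with the pattern, so scoring a new subject needs only the
saved GMP and pattern.

Two non-obvious modelling choices deserve explanation:

**GMP from the reference group only.** Classic SSM centres on the pooled
grand mean; here the reference group defines the centring profile, so target
subjects' residuals carry the group contrast as a mean offset in addition to
their covariance. The pooled variant is available
(`DerivationSettings(gmp_scope="pooled")`).

**Uncentred PCA.** The residual matrix is not re-centred before
decomposition — GMP subtraction *is* the centring step of the model. The
decomposition therefore spans the full residual row space (numerical rank up
to n), scores × componentsᵀ reconstructs the residual matrix exactly when
every component is retained, and per-component VAF sums to 100 %. The
decomposition runs through the n × n Gram matrix, so cost scales with
subject count, not the ~10⁴–10⁶ voxels. Components are sign-oriented so the
target group's mean score is at least the reference group's: higher score ⇒
more target-like, everywhere in the package.

## Component retention and combination

"Components explaining at least 50 % of variance" is read cumulatively: the
smallest prefix of VAF-ordered components whose cumulative VAF reaches the
threshold. The per-component reading (each retained PC alone ≥ threshold)
would almost always keep at most one component; it remains available
(`selection_rule="per_component"`).

Forward stepwise logistic regression (statsmodels `Logit`) starts from the
intercept-only model and adds, at each step, the candidate that most
improves the criterion — AIC by default; a likelihood-ratio entry test at
α = 0.05 is the alternative. Selection operates on raw component scores:
both criteria are invariant to per-candidate affine rescaling, so
standardising would change nothing. An empty selection is a legal outcome
and is reported as "no differentiating pattern".

**Complete separation.** With n = 30 and a strong pattern the logistic MLE
frequently does not exist. A step whose model separates the groups
completely stops the selection with a flag, and the *last finite* model's
coefficients are used — the separated model's coefficient direction is a
max-margin direction that systematically over-weights low-variance
components in the voxel pattern, which is why it is discarded rather than
capped. When the very first candidate separates (so no finite component
model precedes it), that candidate is kept and a lightly ridge-penalised
Newton fit (λ = 1e-4) supplies finite, deterministic coefficients; with a
single component the pattern direction is unaffected by the coefficient
magnitude. Downstream classification thresholds scores, not probabilities,
so separation never destabilises the ROC stage.

The combined pattern is unit-normalised so scores are comparable across
folds and resamples; z-scoring against the reference training group's score
mean and SD (ddof = 1) follows SSM convention.

## Validation

**Bootstrap (default B = 1000).** Subjects are resampled with replacement
within each group, preserving the per-group design, and the entire
derivation is re-run. A repetition succeeds when derivation completes with a
non-empty selection *and* the in-resample scores separate the groups
(one-sided rank-sum p < α). Success so defined measures derivability plus
in-sample separation; because the model was selected to separate its own
resample, it is optimistic and should not be read as type-I-controlled
evidence of a group difference — that is LOOCV's job. Under a strong effect
the success rate is at ceiling; under the null it is high as well, which is
expected given the definition.

**LOOCV.** Each fold removes one subject and re-derives everything — GMP,
PCA, retention, stepwise selection, pattern, reference statistics — on the
n − 1 remainder, then scores the held-out subject as a fold z-score so folds
share one scale. The held-out subject influences nothing in its fold's
model. A fold with empty selection contributes a score of 0 and marks the
report degraded. The pattern "sustains" LOOCV when a one-sided rank-sum test
(target > reference) on the n cross-validated scores rejects at α = 0.05;
the rank-sum choice matches the nonparametric group testing used throughout
the pipeline. Re-deriving the stepwise selection inside each fold (honest
cross-validation) is the default; a frozen-subset variant can be emulated by
fixing `selection_rule` and criterion, but is deliberately not the default.
Under null phantoms the measured sustained rate is at or below the nominal
5 % (ties at zero from empty-selection folds make the test conservative).

**Held-out validation.** Validation subjects are scored with the
full-training model and compared with the reference training scores by the
same one-sided rank-sum test (exact when untied), and classified with the
LOOCV-derived Youden threshold. Validation subjects never enter the GMP,
PCA, selection, bootstrap, or threshold computation; the whole-brain mask is
the one quantity built from all subjects' tissue maps, since it encodes
shared anatomy rather than group contrast.

## ROC, threshold and concordance

AUC uses the rank/pair-counting formula with ties contributing ½, identical
to the trapezoidal area under the threshold-swept curve. The Youden
threshold maximises J = sensitivity + specificity − 1; ties break toward
higher specificity, then higher threshold — certainty of a target call is
preferred — and all co-optimal operating points can be requested.
Classification is strict (score > threshold ⇒ target; a score exactly at the
threshold is reference). PPV and NPV are reported as integer percentages
(half-up), and an empty denominator is reported as undefined, never as 0.
Concordance between two modalities keeps subjects with agreeing calls;
metrics are computed within that subset only, and discordant subjects are
"no call". The pipeline pairs the two highest-AUC modalities by default.

## The phantom generator

The phantom emulates the *statistical* structure the analysis assumes, not
MR physics: an ellipsoidal white-matter core (baseline 1.0) inside a
grey-matter shell (0.7) on a shared grid; a ground-truth pattern that is a
sum of signed Gaussian blobs restricted to the brain; subject images =
baseline + loading × pattern + i.i.d. Gaussian voxel noise; white-matter
lesions as small signed spheres drawn identically for both groups
(structured nuisance uncorrelated with phenotype); and a per-subject global
intensity factor ~ N(1, 0.1) for globally scaled modalities, absent for
intrinsically normalised ones.

Parameters that matter, with defaults:

- `grid_shape = (32, 32, 32)` voxels; the mask then holds ≈ 12.5 k voxels.
- `n_reference/n_target`: 15/15 at the training design; 30/20 for a full
  cohort with validation remainder.
- `effect_amplitude = 1.0` — the target group's mean pattern loading.
  Because blobs are generated with peak amplitude ≈ 1 and *applied* at that
  scale (the stored truth is the unit-norm version), `effect_amplitude` is a
  per-voxel contrast in blob cores, directly comparable to `noise_sd`:
  the default is five times the noise. Applying a unit-norm pattern instead
  would spread the effect over ~10⁴ voxels and put it far below the
  spiked-covariance detection threshold at n = 30 for any method.
- `loading_sd = 0.3` — between-subject spread of pattern expression, giving
  ≈ 3 SD of group separation in score space at the default effect.
- `noise_sd = 0.2` — i.i.d. voxel noise, 20 % of the white-matter baseline.
- `n_blobs = 6`, blob scale σ ~ U(2, 4) voxels (scaled with the grid):
  anatomical covariance patterns live at lobe/nucleus scale, roughly 1/8 of
  the brain's linear extent; much smaller blobs would model focal lesions,
  which the lesion field already provides as nuisance.
- `modalities` — name → kind mapping; all modalities share one truth pattern
  and, with `modality_loading_rho = 1` (default), one latent loading per
  subject; `rho < 1` decorrelates expression across modalities. Voxel noise
  is always independent across modalities. No claim of fidelity to real
  inter-sequence correlation is made — the knob exists because that
  correlation is unknown.
- `lesion_count_range = (0, 5)` per subject, radius 1–2 voxels, amplitude
  ±0.3, white matter only.

One RNG stream per cohort, seeded once; per-subject streams are spawned
deterministically, so identical config + seed ⇒ bit-identical cohorts.

What the phantom does **not** emulate — and hence what passing tests do not
show about clinical data: MR physics and acquisition artefacts, geometric
misregistration, smooth spatially correlated noise, scanner/site effects,
partial-volume tissue probabilities (maps are binary here), and realistic
inter-modality coupling. Recovery rates on phantoms bound the method's
behaviour under its own assumptions, not its clinical accuracy.

## Numerical choices

- Rank truncation in PCA: eigenvalues below `λ_max · 1e-10` are dropped.
- Component sign ties (equal group means) orient the first non-zero loading
  positive; VAF ties keep decomposition order.
- Separation detection: fitted probabilities within 1e-6 of the labels, a
  perfect-separation error/warning from the fitter, or non-finite
  coefficients.
- Rank-sum tests use the exact null when scores are untied, the normal
  approximation otherwise; a fully tied score set returns p = 1.
- All report floats are rounded to fixed precision before JSON
  serialisation, making re-runs byte-identical.
- Tissue threshold 0.1 with intersection-across-subjects masking; union is
  available. Neither a threshold nor the combination rule is standardised in
  the field; intersection guarantees every matrix cell is brain-supported
  for every subject.
- Optional natural-log transform (classic SSM) is off by default:
  MT-derived maps can approach zero, where the log is undefined.

## Problem sizes used by the tests

Unit and pipeline tests run on 16³ grids with 8 + 8 subjects and an effect
ten times the noise (separable by construction); the end-to-end suites sweep
50 seeds of the native 32³, 15 + 15, effect-5×-noise design for recovery and
100 seeds of its null for calibration. The acceptance script runs one full
30/20 study with B = 1000 plus a ten-seed recovery sweep. These sizes are
the package's own choice of a thorough-but-quick default; all scale up by
config.

## Known limitations

- Bootstrap "success" is a derivability-plus-in-sample-separation measure,
  not a calibrated test (see above).
- Affine mismatches between volumes are errors; no resampling or
  registration is provided.
- No confidence intervals on AUC, and no permutation alternative to the
  rank-sum criteria.
- With `gmp_scope="reference_only"` the residuals of the target group are
  not mean-centred; VAF percentages therefore mix group offset and
  within-group covariance, which is intrinsic to this model variant.
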