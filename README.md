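# cpmkit

Connectome-based predictive modeling (CPM) of stable traits — Big Five
personality factors, their superordinate components, fluid intelligence —
from resting-state functional connectivity, as a tested, reusable pipeline
with a synthetic-cohort generator providing known ground truth.

## Who this is for

Researchers who want to study the *methodology* of resting-state
trait prediction — denoising choices, test–retest reliability,
family-aware cross-validation, permutation inference — without access to
restricted imaging data. Every stage runs on synthetic cohorts whose
connectome and trait structure (family structure, subject-stable
fingerprints, confound effects, trait-linked edge sets) is planted and
therefore recoverable, so statistical claims about the pipeline are
testable.

## The method

1. **Denoising.** Parcel-resolved BOLD time series are cleaned with one of
   three standard pipelines: (A) z-score → Legendre detrend of tissue
   references → CSF/WM regression → 12-parameter motion regression →
   Gaussian low-pass (SD = 1 TR) → Legendre detrend → global-signal
   regression; (B) demean/detrend → 0.01–0.08 Hz first-order Butterworth
   band-pass → one combined 36-parameter + spike-regressor model; (C)
   (on ICA-FIX-like input) detrend → CompCor + tissue/whole-brain
   regression with FD/DVARS censoring → band-pass.
2. **Connectomes.** Functional connectivity is the Pearson correlation of
   parcel time series over retained volumes, Fisher z-transformed; runs
   are averaged in z-space into sessions (REST1, REST2, REST12) and the
   upper triangle is vectorized into n(n−1)/2 edges per subject.
3. **Reliability.** Identification success rate (connectome
   fingerprinting), pairwise-similarity test–retest, and behavioral-
   utility test–retest (session-to-session correlation of edgewise
   trait-correlation maps).
4. **Prediction.** Within each leave-one-family-out (LOFO) fold: traits
   are residualized on confounds (OLS fitted on the training fold only);
   edges correlated with the training scores at two-sided p < .01 are
   selected; either a univariate network-strength model (score regressed
   on the sum of selected edge weights, separately for positively and
   negatively correlated edges) or an elastic net (L1 ratio 0.01, penalty
   α picked from 50 values by inner 3-fold CV stratified on score
   quartiles) predicts the held-out family.
5. **Evaluation.** Pooled cross-validated predictions are scored with
   Pearson r, the cross-validated coefficient of determination
   R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)² (which can be negative), RMSD, and
   nRMSD = RMSD / SD(y) = √(1−R²); significance comes from a permutation
   test that shuffles scores between subjects while keeping confounds,
   edges and family-based folds fixed, with p = (k+1)/(n+1).

NEO-FFI scoring (0–4 Likert coding, published reverse-coded item lists,
Cronbach's α, and the PCA extracting the α/β superordinate components) is
included, so questionnaire responses can be carried end to end.

## Worked example

```python
import numpy as np
from cpmkit import synth
from cpmkit.prediction import ModelConfig, predict_cv, cv_runner
from cpmkit.evaluation import permutation_test
from cpmkit.reliability import identification_success_rate

# 200 subjects in 100 families, 60 parcels; a 100-edge network carries a
# cross-subject correlation of 0.3 with the latent Openness trait
tm = synth.LatentTraitModel(signal_effect={"O": 0.3}, n_signal_edges=100)
spec = synth.CohortSpec(n_subjects=200, n_families=100, n_parcels=60,
                        seed=42, trait_model=tm)
cohort, truth, edges = synth.simulate_edges(spec, n_timepoints=300,
                                            sessions=(1, 2))

isr = identification_success_rate(edges[1], edges[2]).isr
print(f"ISR (REST1 -> REST2): {isr:.1f}%")

y = cohort.table["latent_O"].to_numpy()
res = predict_cv(edges[1], y, None, cohort.family_ids,
                 ModelConfig("univariate_pos"))
m = res.metrics()
print(f"cross-validated r={m.r:.3f}, R2={m.r2:.3f}, nRMSD={m.nrmsd:.3f}")

null = permutation_test(cv_runner(edges[1], None, cohort.family_ids,
                                  ModelConfig("univariate_pos")),
                        y, n_perm=199, seed=42)
print(f"permutation p = {null.p_empirical:.4f}")
```

prints

```
ISR (REST1 -> REST2): 100.0%
cross-validated r=0.926, R2=0.851, nRMSD=0.385
permutation p = 0.0050
```

The identification rate of 100% reflects the generator's default
subject-stable fingerprint share; the cross-validated r of 0.93 shows the
LOFO chain recovering the planted 100-edge network (aggregating 100 edges
each carrying r = 0.3 yields a far stronger network-strength predictor);
and p = 1/200 means the observed r exceeded all 199 permutation
replicates.

A command-line interface mirrors the stages (`cpmkit simulate | score |
denoise | fc | reliability | predict | grid | validate`); e.g.

```bash
cpmkit predict --n-subjects 60 --n-parcels 40 --model univariate_pos \
    --target gF --deconfound full --seed 7 --out result.json
```

runs simulate → denoise (pipeline A) → connectome → deconfound → LOFO
prediction on a default cohort (which plants no signal, so the result is a
null: r ≈ 0.01, R² < 0).

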