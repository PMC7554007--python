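# radsurv

Radiomics-based survival modelling for tumor MRI. `radsurv` turns a 3D
image volume plus a tumor segmentation into a 545-feature quantitative
profile, compresses the profile into a handful of latent factors, and fits
and validates Cox proportional-hazards models whose discrimination is scored
by integrated time-dependent AUC (iAUC). It is written for imaging
researchers who want a tested, reproducible implementation of this pipeline
— including the synthetic phantoms and cohorts needed to verify every stage
against known ground truth — rather than a black-box model.

## The pipeline

1. **Feature bank** — 545 named radiomic features per tumor: first-order
   intensity statistics (35), Moran's I and Geary's C spatial
   autocorrelation (2), intensity-volume-histogram AUC (1), morphology (11),
   box-counting fractal features (4), and gray-level co-occurrence (300) and
   run-length (192) texture over a grid of {32, 64, 128} gray-level bins x
   {averaged, merged} direction aggregation x {2D, 3D} neighbourhoods.
   Discretization is fixed-bin-number over the VOI range,
   `g = min(N, 1 + floor(N (x - min)/(max - min)))`, which makes texture
   invariant to monotone-affine intensity maps.
2. **Normalization check** — five gray-level normalizations and a
   per-feature Kendall's-W concordance across conditions quantify how little
   the features depend on the intensity scale.
3. **Consolidation and filtering** — variants of one quantity are averaged
   into 90 core features; interobserver stability is scored by Kendall's W
   against a 0.7 bar; redundancy filtering removes the most globally
   correlated member of any pair with |r| > 0.95.
4. **Factor model** — the correlation matrix is shrunk toward the identity,
   R(λ) = (1-λ)R + λI with λ cross-validated, and maximum-likelihood factor
   analysis fits R ≈ ΛΛᵀ + Ψ; loadings are varimax-rotated and per-patient
   scores are Bartlett estimates F = (ΛᵀΨ⁻¹Λ)⁻¹ΛᵀΨ⁻¹z. Scanner vendor /
   field-strength batch effects are tested by MANOVA on the scores.
5. **Survival models** — Cox models (Efron ties) on factor scores, clinical
   covariates (N-stage, age, gender), log tumor volume, and their
   combination; evaluated by IPCW cumulative/dynamic AUC(t) integrated over
   the event-time window, bootstrap percentile CIs, median-risk Kaplan-Meier
   splits with log-rank tests, and paired-bootstrap model comparison.
   Validation keeps the radiomic signature frozen and recalibrates only the
   clinical coefficients.

Estimator classes follow scikit-learn conventions (`fit` / `transform` /
`predict`, fitted attributes with trailing underscores), so
`RedundancyFilter`, `MLFactorAnalysis` and `CoxRisk` compose with sklearn
pipelines; module-level functions wrap them for script use. A
`synthetic_data` module generates textured ellipsoid phantoms (NIfTI) and
tabular cohorts with known loadings, Cox coefficients and censoring, so
every stage can be checked against ground truth.

## Worked example

```python
import radsurv as rs

# a textured ellipsoid phantom with known geometry
vol, mask, truth = rs.generate_phantom(rs.PhantomSpec(seed=7))
fv = rs.extract_all(vol, mask)           # 545-entry pandas Series
print(len(fv))                            # 545
print(f"{fv['morphology.volume']:.4g}")   # 1.609e+04  (analytic: 1.608e+04 mm^3)
print(f"{fv['morphology.sphericity']:.4f}")        # 0.9651
print(f"{fv['glcm.contrast.b64.merged.3D']:.4g}")  # 15.56
```

The phantom's mesh-derived volume agrees with the analytic ellipsoid volume
4/3·π·abc to 0.1%, and sphericity is close to 1 for a mildly eccentric
ellipsoid. End-to-end on a synthetic two-center study (train n = 102,
validate n = 76, survival signal on two of seven latent factors, weak
clinical signal):

```python
from radsurv.factor_model import MLFactorAnalysis
from radsurv.prognostic_model import run_study, report_frame

train, val, _ = rs.paper_shaped_scenario(seed=1)
feats = [c for c in train.columns if c.startswith("feat_")]
fa = MLFactorAnalysis(n_factors=7, shrinkage="auto").fit(train[feats])

def attach(df):
    out = fa.transform(df[feats])        # frozen training standardization
    for c in df.columns:
        if not c.startswith("feat_"):
            out[c] = df[c]
    return out

rep = run_study(attach(train), attach(val), endpoints=("os",), B=200, seed=0)
print(report_frame(rep).round(3).to_string(index=False))
```

```
endpoint     cohort    model  iAUC  ci_low  ci_high  logrank_p
      os   training radiomic 0.857   0.784    0.910        NaN
      os   training clinical 0.591   0.463    0.707        NaN
      os   training combined 0.878   0.813    0.925        NaN
      os validation radiomic 0.765   0.686    0.860      0.000
      os validation clinical 0.547   0.399    0.670      0.205
      os validation combined 0.769   0.696    0.854      0.000
```

Read: the radiomic factor signature transfers to the held-out cohort
(validation iAUC 0.77 with a significant median-risk log-rank split), the
weak clinical model hovers near chance, and the combined model is at least
as good as either — the qualitative ordering a prognostic radiomics study
aims to demonstrate. An iAUC of 0.5 is no discrimination; 1.0 is perfect
risk ranking.

The same flow is available as a CLI:

```bash
radsurv simulate phantom --seed 7 --out-image img.nii.gz --out-mask mask.nii.gz
radsurv extract --image img.nii.gz --mask mask.nii.gz --out features.csv
radsurv run --seed 1 --out-dir run/      # synthetic end-to-end preset
```

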