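# cystrad

Quantitative-imaging analysis pipeline for grading pancreatic cystic
lesions (high grade vs low grade), plus a synthetic-cohort generator so the
whole pipeline is testable without patient data.

Stages:

1. **Texture features** (`cystrad.texture`) — ROI quantization (equal-width,
   default 32 levels), gray-level co-occurrence matrices over the 13 unique
   3D directions (4 in-plane directions in 2.5D mode) at configurable
   distances, the Haralick correlation statistic plus contrast / entropy /
   energy / homogeneity, and first-order intensity statistics.
2. **Marker screening** (`cystrad.screening`) — Mann-Whitney AUC, empirical
   step-function ROC curves, TPR at a 5% FPR cap (ROC(0.05)), Youden
   operating points, tie-corrected normal-approximation p-values,
   Benjamini-Hochberg FDR, stratified-bootstrap percentile CIs, and
   candidate selection as the union of the top-10-by-AUC and
   top-5-by-ROC(0.05) markers.
3. **Panel building** (`cystrad.panel`) — IRLS maximum-likelihood logistic
   fits on z-scored markers (flagged ridge fallback under separation) and
   an exhaustive AIC search over all non-empty candidate subsets (cap 15).
4. **Validation** (`cystrad.validation`) — two leave-1/3-out schemes:
   scheme 1 refits a fixed panel per stratified 2/3-1/3 split (default 1000
   repeats); scheme 2 re-runs screening + selection + AIC search inside each
   training split (default 10 repeats). Refit-per-draw stratified bootstrap
   (default 1000 draws) gives percentile intervals for the panel AUC and
   Youden index.
5. **PCA view** (`cystrad.pca`) — correlation-matrix PCA with a quantified
   class-separation surrogate (standardized centroid distance).
6. **Worrisome-feature classification** (`cystrad.fukuoka`) — six
   positivity-triggering criteria (main-duct involvement, cyst > 3 cm,
   mural nodules, duct diameter > 5 mm, positive cytology, symptoms) and a
   cohort summary including the benign-among-positives percentage.
7. **Synthetic cohorts** (`cystrad.synthetic`) — Gaussian-random-field
   texture volumes with ellipsoidal ROI masks whose spatial correlation
   length differs by class, binormal feature tables with designed marker
   AUCs (`AUC = Phi(delta/sqrt(2))`), and worrisome-feature records
   generated to exact per-grade criterion margins.

## CLI

Every stage is independently invocable via the `cystrad` entry point:

```sh
cystrad simulate --kind texture  --out runs/tex --seed 1 --n-hg 34 --n-lg 19
cystrad extract  --cohort runs/tex --out runs/features.csv
cystrad screen   --features runs/features.csv --out runs/screen --seed 1
cystrad panel    --features runs/features.csv \
                 --candidates runs/screen/candidates.json --out runs/panel
cystrad validate --features runs/features.csv --scheme 2 --out runs/cv2.json
cystrad pca      --features runs/features.csv --out runs/pca
cystrad simulate --kind fukuoka --out runs/fk --seed 1
cystrad fukuoka  --records runs/fk/fukuoka_records.csv --out runs/fk
cystrad run-all  --features runs/features.csv --out runs/full --seed 1
```

`run-all` executes screen → exhaustive AIC panel → both CV schemes →
panel bootstrap → PCA, writing CSV/JSON artifacts (and a PCA scatter PNG)
stamped with a config hash; a single root seed deterministically derives
every stage seed. Stage parameters can also be given as a YAML config via
`--config`.

Images and masks are read/written as NIfTI; feature tables and records as
CSV (grades `HG`/`LG` or `1`/`0`); reports as CSV/JSON.

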