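# Methods

This note documents the models, conventions and numerical choices behind
`wsimet`, and what the synthetic data generator does and does not emulate.

## Problem setting

Primary cutaneous squamous cell carcinoma (cSCC) metastasizes in a small
fraction of patients, and histopathological staging predicts that risk
poorly. The pipeline implemented here analyzes hematoxylin-eosin whole-slide
images (WSIs) of annotated primary tumors to separate tumors that
metastasized rapidly (within 180 days of diagnosis) from tumors that never
metastasized during five years of follow-up, and combines the resulting
image-level prediction with classical risk factors (Clark's level 5,
diameter ≥ 30 mm) into an ordinal risk-factor model (RFM) evaluated by
odds ratios, concordance AUROCs and Kaplan–Meier survival.

## Tiling and tissue detection

Slides are cut into a non-overlapping grid of square tiles (512 or 1024 px)
from the image origin; partial edge tiles are discarded rather than padded,
to avoid diluting labels with background-heavy fragments. A tile is *valid*
when more than 50% of its pixels are tissue and a *tumor* tile when more
than 50% fall inside the annotation mask; both rules are strict majorities,
so a fraction of exactly 0.5 does not qualify. Tumor tiles inherit the
slide's cohort label, and each is resized to 299 × 299 px (bilinear — the
target size is fixed, the kernel is a free choice) before classification.

Tissue is detected by a combination of a fixed binary threshold and Otsu's
method: a pixel is tissue iff its ITU-R 709 grayscale value lies below
*both* the fixed background cutoff (220/255) and the per-image Otsu split.
The fixed cutoff protects nearly empty slides, where Otsu would split
background noise; on a constant image, where Otsu is undefined, the fixed
cutoff alone applies. Manual exclusion regions are simply zeros in the
annotation mask.

Three input-sampling modes exist: every tumor tile (default), tiles at the
invasive front (tile-level 4-adjacency between tumor and non-tumor tiles;
sides `inside`, `outside` or `both` — an annotation covering the whole grid
has no boundary), and disjoint random stacks of *n* tiles per slide
(leftovers dropped, so a dataset of T tiles yields Σ⌊T_s/n⌋ stacks).

## Classifier

Tiles are classified by a lightweight residual network designed to train in
minutes on one CPU: a fixed average-pooling trunk converts each tile into a
7 × 7 lattice of per-channel means and grayscale standard deviations plus
global grayscale statistics (198 features), followed by learned residual
dense blocks and a classification head of one dense layer with heavy
dropout (p = 0.5) and a sigmoid unit, trained with binary cross-entropy.
Depth presets (`tiny`: 4 blocks × 32 wide; `resnet18-like`: 8 × 128;
`resnet50-like`: 16 × 256) trade capacity for runtime; `tiny` is the
default and is what the bundled tests exercise. Optimization is Adam
(lr 10⁻³, batch 64, weight decay 10⁻⁴), seeded and deterministic; these
optimizer settings have no external reference values and are fixed here
for reproducibility. Per-class loss weighting for the 59 : 22 slide
imbalance is available but off by default.

Cross-validation is patient-exclusive and stratified by cohort: patients
are shuffled within cohort and dealt round-robin into k folds (every cohort
must have ≥ k patients), so all tiles of a patient share one fold and
per-fold cohort counts differ by at most one patient. Every tile receives
exactly one out-of-fold (OOF) probability, produced by the model whose
validation fold holds the tile's patient. In stack mode, member-tile
features are averaged, the model predicts per stack, and the stack
probability is broadcast to its members for slide mapping.

Color augmentation (flips, right-angle rotations, HSV jitter) is provided
for training on real scans, where scanner and staining variation matter; it
is off in the synthetic pipeline, whose generator has no such variation. A
scan-batch filter restricts analysis to one scanning session, the remedy
for batch-label confounding.

## Aggregation

OOF probabilities p are mapped to scores s = 100·p − 50 ∈ [−50, 50] and
arranged on the slide's tile grid. The grid is smoothed with a median
filter of window 2: the window anchored at cell (r, c) covers rows
[r, r+2) × cols [c, c+2), clipped at the borders, and the cell value is
replaced by the median of the valid scores inside (an even count of values
gives the mean of the two central order statistics; a window with no valid
neighbor leaves the cell unchanged). Forward anchoring with border clipping
is one of several defensible conventions; it is fixed here so the smoothed
grid is reproducible, and hand-enumerated cases pin the behavior in tests.

The slide score is the arithmetic mean of the smoothed valid scores, and
the slide is called metastatic iff its mean score strictly exceeds 0; a
mean of exactly 0 is conservatively called non-metastatic. This
sign-of-mean rule is the operational form of a slide-level majority vote
over scaled predictions; a literal tile-count majority is available as
`vote="count"`. ROC curves and AUROCs use the tie-corrected rank statistic
(W + T/2)/(n₁n₀). Probability maps paint each valid tile with a diverging
blue-white-red palette over [−50, 50] (red = high metastasis score) and
leave unannotated area white.

## Risk statistics

For a 2 × 2 table the unadjusted odds ratio is (a·d)/(b·c) with the Woolf
log-method 95% CI, exp(ln OR ± 1.96·√(1/a + 1/b + 1/c + 1/d)); the
multiplier 1.96 (rather than the exact quantile) matches the convention of
the published intervals. Any zero cell makes the OR or its variance
undefined and the result is reported not-estimable — no continuity
correction, mirroring the NA entries of the source risk table. Reference-
coded logistic regression (maximum likelihood via IRLS) is also provided;
for a single saturated categorical predictor its per-level ORs equal the
cross-product ratios, which the tests verify, and levels completely
separated from the reference are flagged not-estimable.

Ordinal predictors (staging systems, risk-factor counts) are scored by the
concordance AUROC on grouped counts — the probability that a random case
sits at a strictly higher level than a random control, ties counted half.
RFMs count, per tumor, how many of a selected set of binary risk factors
are present (e.g. AI-metastatic, Clark 5, diameter ≥ 30 mm); tumors missing
any selected factor are excluded from that model only, so denominators vary
per variable rather than listwise. Association tests use Fisher's exact
test for 2 × 2 tables whose smallest expected cell is ≤ 5 and the Pearson
χ² test otherwise; Pearson correlation matrices use pairwise-complete
observations, with zero-variance columns flagged undefined.

One published inconsistency is deliberately not reproduced: the
alternative "≥ 20 mm" diameter grouping prints OR 14.39, but the
cross-product of its own printed counts is (17·46)/(13·5) = 12.03. The
formula is implemented; the printed value is treated as a typographical
artifact and targeted nowhere.

## Survival

Kaplan–Meier estimation (delegated to lifelines) uses days from primary
diagnosis, administrative censoring at 1826 days (5 years), and the
standard convention that events precede censorings at tied times.
Five-year survival is evaluated at exactly 1826 days as a right-continuous
step function; evaluation beyond the last observed time returns the last
value with a warning. The median is the smallest t with S(t) ≤ 0.5, or
not-reached. Greenwood confidence bands are omitted by default.

## Synthetic data

Real slides and patient records from the source cohorts are not available,
so the generator produces stand-ins with the structure the analysis needs:

- **Slides** (default 4096 × 4096 px, so 512-px tiles form an 8 × 8 grid —
  large enough to exercise smoothing, small enough for CPU testing): a
  near-white background (≈245), a pink tissue field extending ~18% beyond
  the annotation polygon, and dark nucleus-like ellipses. Inside the
  annotation, nucleus density (base 1.5·10⁻⁴/px) and radius (base 5 px)
  are scaled by (1 + 1.2·e) and (1 + 0.5·e) for the rapid-metastasis
  cohort, where e = `texture_effect`; e = 0 makes the class-conditional
  pixel statistics identical in expectation, and the slow-metastasis
  cohort always reuses the non-metastatic texture. Tones are set so the
  dominant grayscale split lies between tissue (≈162) and background, not
  at the nuclei, keeping Otsu on the intended boundary.
- **Cohort tables** sample each clinicopathological variable independently
  from the published per-cohort level frequencies (n = 59 non-metastatic,
  n = 22 rapid metastasis; the slow cohort, which has no published
  baseline table, reuses the non-metastatic marginals). Independence
  across variables is a simplification: real staging variables are
  strongly correlated, so these tables exercise the statistical machinery,
  not clinical joint distributions.
- **Survival** times are exponential per stratum with default hazards
  matched to the reported medians (1.2 years rapid, 3.4 years slow) and a
  ~70% five-year overall survival for the non-metastatic, mostly elderly
  cohort, censored at 1826 days. The disease-specific endpoint flips a
  per-stratum fraction of events to censored (1.0 non-metastatic, 0.1
  rapid, 0.2 slow), making DSS events a subset of OS events, as a deduced
  cause of death would.
- **Count fixtures** ship the published case/control tables verbatim, so
  the risk statistics are exactly reproducible offline.

Passing tests on these data show that the pipeline recovers a planted,
monotone texture signal and that every statistic matches its oracle; they
do not show that real scanner variation, stain heterogeneity, or the
actual morphology of metastatic cSCC would be handled equally well.

## Problem sizes and tolerances in the bundled checks

The signal-recovery check runs the full pipeline at texture effect 1 with
20 slides per class (8 × 8 grids, `tiny` depth, 6 epochs, 4-fold CV) and
expects slide-level AUROC > 0.9; the null check uses texture effect 0 with
50 slides per class and expects AUROC within [0.35, 0.65], a ±2.6σ band
around chance for 50 + 50 slides. Kaplan–Meier recovery uses two
exponential strata with designed five-year survival 0.97 and 0.40 (n = 400
each, tolerance ±0.05). Concordance oracles compare against brute-force
all-pairs enumeration to 10⁻¹², and the published odds ratios and AUROCs
are asserted at the printed precision (2 and 3 decimals, half-up
rounding).

## Known limitations

- The classifier's pooled-feature trunk is blind to structures smaller
  than its pooling cells; it is intended for planted texture effects and
  desk-scale experiments, not for state-of-the-art WSI classification.
- Proprietary scanner formats are out of scope; inputs are plain
  TIFF/PNG images with aligned mask images.
- The real cohorts' slide-level AUROC and survival curves cannot be
  reproduced without the patient data; the synthetic recovery properties
  above stand in for them.
- Multivariable (adjusted) logistic models are not implemented; the
  source analysis reports only unadjusted ORs.
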