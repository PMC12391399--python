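# Methods

## Scope and model

`lfqpipe` analyzes label-free quantification (LFQ) proteomics
experiments of the form *k* isolates × {control, herbicide-treated} ×
*n* biological replicates, starting from a per-protein-group intensity
table (MaxQuant `proteinGroups` dialect: one accession column plus one
intensity column per sample). The statistical model is the standard
per-protein two-group comparison on normalized log2 abundances, with
missing-not-at-random (MNAR) dropout handled by probabilistic minimum
imputation. Around the core test the package provides set overlap
(Venn regions) across isolates, descriptive GO categorization,
PCA ordination, and the spectrophotometric physiology calculations
used alongside such experiments (Evans blue viability, chlorophyll and
carotenoid quantification).

## Transformation chain

Applied in fixed order; every step appends its parameters to a
provenance list, and replaying the provenance on the raw matrix
reproduces the normalized matrix bit-for-bit (the imputation seed is
part of the provenance).

1. **log2 conversion.** Zeros, blanks and non-numeric cells are read
   as missing, never as measured zeros: in LFQ a zero means the
   peptide signal fell below detection. Base 2 is the default so that
   downstream fold-change thresholds are log2 ratios and the volcano
   p-axis cut at p = 0.05 equals −log2(0.05) = 4.32.
2. **Per-sample centering.** The mean of each sample's valid (present)
   log2 values is subtracted from its valid cells. Median centering is
   available (`stat="median"`) but the mean is the default.
3. **Per-sample width scaling.** Each sample's valid cells are divided
   by their standard deviation (ddof = 1), equalizing acquisition
   dynamic range across samples. IQR scaling is available as an
   option; the SD is the default because the imputation model below is
   stated in SD units. The per-sample widths are recorded in
   provenance (see *Fold-change units* below).
4. **Validity filter.** A protein is retained if at least
   `min_valid_per_group` (default 2 — the minimum for which a variance
   exists) of its values are present in at least one design group.
   A stricter *per-contrast* form of the same rule is available in
   `run_de_table` (see *Recommended triplicate settings*).
5. **Probabilistic minimum imputation.** Each missing cell in sample
   *s* is drawn independently from N(μ_s − 2.0·σ_s, (0.3·σ_s)²), where
   μ_s and σ_s are the mean and SD of the sample's valid values: low
   abundance is modelled as sitting two SDs below the observed
   distribution, resampled with width 0.3·σ_s. Both parameters are
   configurable (`down_shift`, `width`). The reference distribution is
   per-sample, not global, consistent with the per-sample scope of the
   two normalizations. Imputation happens after centering/scaling and
   imputed cells are not re-centered — re-centering would shift the
   down-of-the-mean semantics the model states. Under the default
   chain σ_s = 1 at imputation time, so computing σ_s before or after
   scaling coincides. A seed is mandatory whenever missing cells
   exist; draws come from a named `numpy` generator recorded in
   provenance.

## Differential expression

Per protein, treated vs control within one isolate:

- **Variance gate.** A two-sided F-test (larger sample variance over
  the smaller, matching dfs) decides homoscedastic vs heteroscedastic
  at level `alpha_f` (default 0.05). A protein with zero variance in
  exactly one group goes to the heteroscedastic branch (a pooled df
  would overstate certainty); zero variance in both groups is
  degenerate and the protein is excluded with a logged reason.
- **Gated t-test.** Homoscedastic → pooled-variance t
  (df = n₁ + n₂ − 2); heteroscedastic → Welch t with
  Welch–Satterthwaite df. Two-sided p-values throughout.
- **Fold change.** Difference of group means in log2 space (treated −
  control), i.e. the log2 of the intensity ratio; "up" means higher
  under treatment.
- **Volcano classification.** `up` iff log2FC > fc_threshold and
  p < p_threshold (default 1 and 0.05); `down` symmetric; the boundary
  |log2FC| = threshold is excluded by default (`strict=True`), with an
  inclusive variant behind a flag. No multiple-testing correction is
  applied to the classification; Benjamini–Hochberg q-values can be
  added as an annotation column (`adjust=True`) but never alter the
  class.
- **p-axis.** The volcano y-axis is −log2(p), the transform under
  which the p = 0.05 cut-off is 4.32. The base is configurable.

### Fold-change units after width scaling

Width scaling divides each sample by its log2 SD, so fold changes in
the normalized matrix are measured in *pooled SD units*, not raw log2
units. A threshold stated on the raw scale (the conventional two-fold
cut, |log2FC| = 1) should be translated onto the scaled axis as
`1 / median(sample widths)`; `preprocess.scale_widths` returns the
recorded widths for exactly this purpose, and the examples and the
acceptance script use it. With a realistic dynamic range (log2 SD ≈ 2)
the translated cut is ≈ 0.5 scaled units.

### Recommended triplicate settings

With only three replicates per group, two failure modes dominate power
losses: (i) contrasts where most cells on one side are imputed — the
fold change collapses toward the down-shift and the comparison is
between imputation artifacts; (ii) a single imputed low-tail cell in
an otherwise clean group inflates that group's variance, trips the
F-gate, and sends the protein to a Welch test with df ≈ 2. The
settings the recovery analyses in this package use, frozen after a
one-time calibration on the synthetic generator, are therefore:

- `run_de_table(..., min_valid_per_group=3)`: require one fully
  observed group per contrast (the common triplicate LFQ filter);
- `alpha_f = 0.01`: a conservative gate, because at n = 3 the F-test
  is noisy and routing borderline proteins to Welch df ≈ 2 costs far
  more power than tolerating mild variance inequality in a pooled test.

Package defaults remain `min_valid_per_group=2` (global) and
`alpha_f = 0.05`.

## Set overlap and GO summarization

Up/down accession sets per isolate (accession string equality defines
identity; no isoform collapsing) are partitioned into the 2^k − 1
exclusive Venn regions; region counts always sum to the union size.
Tables entering a joint Venn must carry identical thresholds — the
extraction refuses mixtures.

GO summarization is descriptive counting against a user-supplied
(accession, GO ID, aspect, term name) map: a term's count is the
number of listed proteins directly annotated to it. No DAG ancestor
propagation and no live database lookups — determinism and offline
testing take precedence; proteins absent from the map are reported as
unannotated. A hypergeometric over-representation mode exists as a
clearly labelled extension, off by default.

## Ordination

PCA of the complete (imputed) matrix with samples as observations and
proteins as features, mean-centred per feature, via SVD. No
per-feature unit-variance scaling by default: sample-level
normalization upstream already equalizes dynamic range. Components are
ordered by variance, fractions of total variance are reported, and a
deterministic sign convention (largest-magnitude loading positive)
makes outputs platform-stable. A silhouette of control vs treated
along PC1 quantifies condition separation. Supervised projections
(PLS-DA) are deliberately out of scope.

## Physiology

- **Evans blue viability.** Mortality = 100 × A600(sample) /
  A600(heat-killed control); the heat-killed control approximates 100%
  mortality. Raw values above 100% (stronger staining than the
  control) are clipped and QC-flagged; viability = 100 − mortality.
- **Pigments.** 80%-acetone extract absorbances at 663, 646 and
  470 nm, each corrected by subtracting the 720 nm reading (turbidity /
  colored-compound baseline; subtraction makes the result exactly
  invariant to a uniform offset). Defaults are the standard
  80%-acetone coefficient set — chl a = 12.21·A663′ − 2.81·A646′,
  chl b = 20.13·A646′ − 5.03·A663′, carotenoids = (1000·A470′ −
  3.27·chl a − 104·chl b)/198, all µg/mL extract — exposed as a
  configurable coefficient table so other published sets can be
  swapped in. Yields per culture volume multiply by the
  extract-to-culture volume factor; per-cell contents divide by cell
  density. Negative corrected absorbances (near-blank extracts) are
  QC-flagged, not fatal. Fv/Fm is consumed as instrument-reported
  values; no fluorescence-trace computation.

## Synthetic data generator

The generator defines the test conditions and is not tuned per run:

- Design: 3 isolates × {0, 10 µM} × 3 biological replicates (the
  layout of the targeted experiment class), configurable.
- Baseline log2 abundance ~ N(20, 2) per protein — a fixture
  convention mimicking LFQ dynamic range, not an empirical claim.
- Within-group SD 0.3 (log2), optionally unequal between conditions to
  exercise the F-gate.
- A `de_fraction` minority of proteins (default 5%) carries a ±2.0
  log2 treatment effect, shared across all isolates by default; a
  `venn_design` map plants exclusive/shared structure across isolate
  subsets instead.
- MNAR dropout: cell with true log2 abundance *a* goes missing with
  probability logistic(−slope·(a − midpoint)), defaults midpoint 16.5
  and slope 1.0 — chosen once to put overall dropout near 10% (within
  the "modest, ≤ 20%" regime) and concentrate it in the low tail.
  Dropout probability is non-increasing in abundance by construction.
- Physiology fixtures invert the forward pigment equations from drawn
  true concentrations (treated samples bleached to 40%), add a random
  720 nm baseline and Gaussian read noise; at zero noise the pigment
  equations recover the truth exactly.

What the generator does **not** emulate: peptide-level roll-up,
correlated protein co-regulation, batch effects, intensity-dependent
variance (heteroscedasticity across the dynamic range), or
contaminant/decoy rows. Passing recovery tests therefore demonstrates
the statistical machinery is correct under the assumed model, not that
any real-data search result is reproduced.

## Problem sizes and numerical choices

Test and acceptance runs use 300–2,000 proteins × 18 samples — large
enough for stable Monte-Carlo bounds (binomial SDs at n = 1,000,
10,000 imputation draws) while keeping suites fast. Tolerances: oracle
equivalence of test statistics at 1e-10 relative; PCA variance against
an eigen-decomposition oracle at 1e-8; exact-arithmetic identities
(offset invariance, zero-noise inversion, mortality normalization) at
1e-9 absolute or better. p-values are clipped to the open interval
(0, 1] before the −log2 transform. Ties in GO output are broken by
GO ID; Venn region frames sort by region size then label.

## Known limitations

- Minimum imputation biases fold changes toward the down-shift for
  proteins with heavy one-sided dropout; such proteins are better
  excluded (per-contrast validity rule) than tested.
- The F-gate at n = 3 has weak power and a high false-routing rate;
  `alpha_f` matters more than it would at larger n.
- Raw p < 0.05 classification (no FDR control) follows the targeted
  analysis convention; q-values are reported only as annotation.
- GO counting is not enrichment: counts depend entirely on the
  supplied map's coverage.
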