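# Methods and design notes

This note documents the models behind each stage, the defaults and why
they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that matter for reproducing
results.

## Fingerprinting

**Peak model and integration.** Detected peaks are local maxima above a
height and prominence threshold (scipy `find_peaks`); each peak is
integrated trapezoidally between the signal minima flanking it. Merged
peaks are *not* split by valley-drop; templates closer than 3σ trigger a
generator warning instead. Baseline handling is limited to whatever the
flanking-minima bounds absorb — no dedicated baseline-correction
algorithm is included.

**Retention-time calibration.** Run-to-run drift in HPLC is dominated by
a coherent run-wide stretch (flow and gradient variation), so late peaks
can drift by far more than the 0.10 min matching window while the
chromatogram stays internally consistent. Calibration therefore works in
two steps that mirror manual practice:

1. *Scale correction.* Candidate run-wide scale factors are formed from
   retention-time ratios between the batch's five largest peaks and the
   consensus batch's five largest; the candidate that pairs the most
   consensus anchors (smallest median residual on ties) wins. Using
   cross-ratios rather than the single largest peak makes this robust to
   a secondary peak occasionally outgrowing the dominant one — which a
   145 % area RSD makes a real possibility.
2. *Multi-point refinement.* The eight largest consensus peaks act as
   anchors; after an affine refit the batch is warped piecewise-linearly
   through the matched anchor pairs. Outside the anchor span the affine
   fit is extrapolated (clamping would collapse distinct outer peaks).
   Fewer than three paired anchors ⇒ scale-only correction.

Calibrated retention times live on the consensus batch's scale, not on
any absolute truth; comparisons against generator ground truth must use
relative retention times.

**Common-peak matching.** Greedy centroid-seeded clustering: candidate
seeds are visited in descending area order (ties by smaller RT); a seed
claims, from every batch, the nearest unassigned peak within the window
of the running centroid (median of members so far). Only clusters with
exactly one member from *every* batch count as common peaks. A seed that
fails to complete a cluster is retired, so non-common peaks are consumed
deterministically. Matching is order-independent for distinct areas and
idempotent on already-matched tables.

**Reference fingerprint and similarity.** The reference is the
element-wise *lower* median across batches (deterministic for even batch
counts, always an observed value). Similarity is the cosine (congruence
coefficient) between a batch's common-peak area vector and the
reference's, rounded to 3 decimals for reporting; a Pearson-correlation
variant is available via `metric="correlation"`. Cosine is symmetric,
scale-invariant and 1 exactly iff the vectors are proportional.

**Reference peak S.** Auto-selected as the common peak with the largest
median area — the dominant, stable peak of the assay. Relative RTs and
areas divide each batch's row by that batch's S value.

**RSD.** One definition package-wide: sample standard deviation (n−1)
divided by the mean, in percent. The quantification module's validation
reporting reuses `fingerprint.rsd`.

## Chemometric screening

**PCA.** Always on the correlation matrix (raw input is z-scored with
n−1 standard deviations first), so eigenvalues sum to the number of
variables p and variance contributions are λ/p. Loadings are
eigenvector·√λ; per-variable communalities over all components equal 1.
Eigenvector sign is fixed so the largest-magnitude loading per component
is positive, which reproduces conventional all-positive first-component
loadings on content data. Scores are projections of the z-scored data
onto eigenvectors, so score variances equal eigenvalues.

**OPLS-DA.** NIPALS-style: for each orthogonal component, the weight is
the part of the X-loading orthogonal to the y-predictive weight
w ∝ Xᵀy; X is deflated by the orthogonal component, then one predictive
PLS component is fitted on the deflated matrix. Initialization comes
from the class-code vector, so the fit is deterministic. Orthogonal
scores have exactly zero covariance with y by construction. One
orthogonal component is the default; R²Y and a 7-fold sample-wise
cross-validated Q² are reported but not used for auto-selection. In the
one-component limit the predictive scores coincide with PLS1 scores on
the deflated matrix (tested against scikit-learn's PLS).

**VIP.** Computed on the predictive component only:
VIP_j = √(p·w_j²) with unit-norm weights, hence mean(VIP²) = 1.
Marker selection uses the strict inequality VIP > 1.

**Class labels.** The two-class grouping for OPLS-DA is a caller
decision (e.g. wild vs. cultivated); the pipeline's synthetic default
splits batches in half. No grouping is inferred from the data.

## Binding screen

The activity percentage compares the observed fluorescence of the
protein+ligand mixture (F_D) against the additive expectation
F_B + F_C − F_A of its parts (the buffer background F_A is counted twice
in F_B + F_C):

AP = (F_B + F_C − F_A − F_D) / (F_B + F_C − 2F_A) × 100.

AP is scale-invariant, strictly decreasing in F_D, 0 under perfect
additivity and 100 when the mixture is quenched to the buffer-only
level (F_D = F_A). Negative values (enhancement) and values above 100
(over-quench) are reported unclipped because ranks are taken after
Z-normalization and clipping would distort them. AP is computed on
replicate means; replicate-wise APs are retained for spread reporting.
A non-positive denominator marks an invalid assay and raises.

## Quantification

Unweighted OLS calibration of area on concentration (a 1/x-weighted
option exists but is off by default — the published curves are
unweighted). Inversion is (area − intercept)/slope; areas below the
intercept map to content 0 with a below-LOD warning rather than a
negative value, and concentrations outside the fitted range warn about
extrapolation. Content is c·V·dilution/m with defaults m = 0.5 g,
V = 20 mL, dilution 1. Spike recovery is (measured − original)/added ×
100. Instrument conditions (gradient, injection volume) are metadata
only and never enter computation.

## Quality evaluation

**Entropy-weighted TOPSIS.** The literature names these steps without
printing formulas, so the canonical variant was adopted and validated
against the published intermediate tables:

- min-max normalization per criterion (all three contents are
  benefit-type; cost-type flipping is supported but unused);
- proportion matrix p_ij = x̃_ij / Σ_i x̃_ij (column-stochastic), with
  the 0·ln 0 := 0 convention — min-max creates exact zeros;
- entropy e_j = −(1/ln n) Σ p_ij ln p_ij, divergence d_j = 1 − e_j,
  weights w_j = d_j/Σd;
- weights applied **to the normalized matrix** (v = w ⊙ x̃), per-column
  max/min ideals, Euclidean distances, closeness C = d⁻/(d⁺ + d⁻).

The alternative of weighting the proportion matrix (v = w ⊙ p) is
selectable via `variant="proportion"`. On the packaged 44-batch table
the normalized variant reproduces the published closeness endpoints
exactly at 3 decimals (0.953/0.043) while the proportion variant gives
0.952/0.044; both agree on the best and worst batch. The normalized
variant is therefore the calibrated default.

**Composite score.** Standardize → correlation PCA → first-PC score
Y = Σ v_j X_j → F = (λ₁/p)·Y. Coefficients are always recomputed from
the eigendecomposition, never hard-coded. Y has mean 0 and F/Y is
constant across batches; the score is invariant to affine rescaling of
any raw content column.

**Grading.** Agglomerative clustering with Euclidean distance on
z-scored contents plus their total, average linkage by default (Ward is
the documented fallback), cut at k = 3. Grade numbers are reassigned so
grade 1 has the highest mean of the supplied ordering score (TOPSIS
closeness or composite score; mean total content if none is given). On
the packaged table both average and Ward linkage isolate the same
15-member top grade.

**Ranks.** Computed at full precision (internal values are never
rounded; rounding to 3 decimals happens only in reports), descending,
with first-occurrence order on ties.

## Synthetic data: what it emulates and what it does not

The generator's defaults state the study-scale world: 44 batches, 25
Gaussian peak templates over a 5–75 min gradient, retention-time scatter
of 2 % RSD (inside the reported 0.635–3.917 % validation band),
per-template lognormal area RSDs spanning the reported 19.439–144.854 %
band (assigned so the dominant peak is the most stable), triplicate
four-control plates with 5 % multiplicative noise and quench fractions
(0.8, 0.7, 0.6, 0.2, 0.1), and a 1.75× content advantage for the
high-quality group — the middle of the reported 1.5–2× wild/cultivated
contrast. The default seed 20251106 is arbitrary but documented; every
generator is bit-reproducible given (config, seed).

Retention-time scatter is realised as a coherent per-batch scale factor
(sd = configured RSD) plus small incoherent per-peak jitter (sd
0.01 min). The coherent part models gradient/flow drift and is what
multi-point calibration removes; the incoherent part stays within the
matching window. Area variation is lognormal because the reported RSDs
reach ~145 % and areas must remain positive.

Not emulated: peak tailing (pure Gaussians), detector saturation,
gradient dwell effects, column chemistry, wavelength dependence, and
valley-drop integration of merged peaks. Consequences worth knowing:

- At the top of the stated area-RSD band a single lognormal draw can
  inflate a mid-sized peak ~10–30-fold (a ≳3.5σ event among 1100
  draws). Matching still resolves all 25 common peaks, but that batch's
  cosine similarity can dip below 0.95 for some seeds — exactly the
  behaviour huge area RSDs imply. The recovery test pins the documented
  default seed.
- Similarly, the same tail can push a small peak below the detection
  threshold in one batch of 44, in which case it is, by definition, not
  a common peak for that seed.

A green synthetic test therefore establishes correct mechanics
(matching, calibration, statistics) under realistic scatter; it does not
certify performance on tailed, saturated or co-eluting real-world
chromatograms.

## Numerical conventions

- Standard deviations are sample (n−1) throughout; z-scores use them.
- Lower median for even batch counts in the reference fingerprint.
- Similarity reported at 3 decimals; all internal computation at full
  precision.
- Lognormal draws are mean-preserving (μ_log = ln m − σ_log²/2).
- Seeds derived from a config seed use fixed small offsets (+1 plates,
  +2 contents) so stages are independently reproducible.

## Known limitations

- Common-peak matching requires presence in every batch; one bad batch
  (or an extreme low-tail area draw) removes a peak from the common set
  rather than imputing it.
- The OPLS-DA two-class grouping must be supplied; no multi-class
  support.
- No LOD/LOQ estimation, no peak-purity checks, no alternative MCDA
  methods (AHP, VIKOR), no bootstrap uncertainty on ranks.
- Grey relational analysis, mentioned alongside TOPSIS in parts of the
  quality-evaluation literature, is not implemented.
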