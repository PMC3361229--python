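# Methods and design notes

## The classification model

The spectra table is an N×p absorbance matrix **X** (p ≈ 750 channels
after range restriction) with B = 3 classes. Class membership is one-hot
encoded into **Y** (N×B) and a PLS2 regression of **Y** on mean-centered
**X** is fitted by NIPALS with deflation; a new spectrum is assigned to
the class whose predicted response is nearest to 1 (argmin |ŷ_j − 1|, not
argmax ŷ_j — the two differ when responses overshoot 1; exact ties go to
the lowest class index with a warning). Mean-centering is the only
response/feature scaling; autoscaling is deliberately not applied, since
per-channel variance in NIR spectra is dominated by baseline, not
information.

### Complexity selection

RMSE_MCCV(k) is estimated from `n_splits = 100` Monte-Carlo splits, each
leaving out `leave_out_fraction = 0.3` of the training rows, stratified by
class (plain uniform resampling is available by flag; stratification is
the default because at N = 75 a 30 % uniform hold-out would occasionally
strip a class from the kept set). One PLS2 fit at `k_max` per split serves
all k: NIPALS scores of held-out spectra are cumulative in k through the
rotation matrix R = W(PᵀW)⁻¹, so predictions at every intermediate
complexity come from the same deflation path (this is why NIPALS was
chosen over SIMPLS). Squared errors are pooled over splits and response
columns. The F-test then takes k* = argmin RMSE and selects the smallest k
with

    F(k) = (RMSE(k)/RMSE(k*))² ≤ F_{1−α}(n_pred, n_pred),   α = 0.25,

with n_pred the pooled hold-out prediction count on each side. The exact
degrees-of-freedom convention for this F-test varies in the literature;
the pooled-count convention is fixed here, documented, and config-exposed.
Since F(k*) = 1 always passes, selection never exceeds the argmin.

## Robust outlier screening

Each class is screened separately on raw, range-restricted spectra
(preprocessing is a modeling choice; the screen should see the
measurement as acquired — a flag allows screening preprocessed spectra).
The fit is a projection-pursuit + MCD hybrid for p ≫ N:

1. project onto the affine span of the data (thin SVD);
2. rank samples by Stahel–Donoho outlyingness over directions through
   pairs of samples (capped at 250 directions, seeded) and keep the
   h = ⌈0.75·N⌉ least outlying;
3. classical PCA of that subset gives the initial k-dim subspace;
4. in the k-dim score space, concentrate the h-subset with MCD C-steps,
   apply the (h/N) consistency factor, then reweight at the χ²_{k,0.975}
   gate. Samples far off the initial subspace — orthogonal distance above
   max(Wilson–Hilferty 0.975 cutoff, 2·median) — are barred from the
   reweighted set so that a *cluster* of orthogonal outliers cannot vote
   its own direction into the model. The reweighted center and covariance
   are re-estimated in the full span, and its top-k eigenpairs (with the
   0.975 reweighting consistency factor) give the final center, loadings
   and eigenvalues.

Plain one-step reweighting without the C-steps and the full-span
re-estimate was measurably miscalibrated on this data shape
(eigenvalues shrunk ~3×, clustered outliers absorbed); both refinements
are standard moves in the robust-covariance literature.

Distances and cutoffs: SD_i = √(Σ_j t_ij²/λ_j) with cutoff
√χ²_{k,1−α}; OD_i is the residual norm with the Wilson–Hilferty cutoff
(m̂ + ŝ·z_{1−α})^{3/2} on OD^{2/3}, m̂/ŝ estimated by median and
1.4826·MAD. α = 0.05 for both cutoffs ("large" means strictly greater;
a distance exactly on its cutoff is "not large"). Exclusion policy: only
orthogonal outliers and bad leverage points are dropped; good leverage
points extend the class model and are retained.

Two finite-sample corrections matter at N ≈ 40, p ≈ 750:

* **Support shrinkage.** The k-dim fit shrinks the residuals of exactly
  the samples that entered the reweighted estimate; `diagnose_class`
  divides their OD by √(1 − k/n_support) before cutoffs are computed.
  Without it the flagged fraction roughly doubles.
* **PRESS normalisation.** The subspace dimension is chosen by 5-fold
  cross-validated reconstruction error with a 10 % robustness trim.
  PRESS(k) is divided by (p − k): any estimated k-dim subspace removes
  ~k/p of held-out noise energy, so the unnormalised curve drifts
  downward even on pure noise. The smallest k within 5 % of the minimum
  wins ("significantly better" is read as this relative-tolerance rule;
  it is config-exposed).

Even so, the clean-data exclusion rate runs above the nominal α when the
within-class structure is genuinely higher-dimensional than the fitted
subspace (as with this generator's drift, and as in real NIR screens,
which typically flag 3–10 % of a clean-looking class): the OD tail then
reflects un-modelled structure, not estimator error. The cutoffs
calibrate to α ± Monte-Carlo error when the residuals are well specified
(verified in the test-suite on exact χ² residuals).

## Kennard–Stone splitting

Greedy max-min Euclidean selection: initialise with the most distant
pair, then repeatedly add the candidate whose minimum distance to the
selected set is largest; ties break to the lowest index (the algorithm is
otherwise tie-order-ambiguous; the rule makes splits bit-reproducible).
The split runs within each class and the selections are merged (default
25 training samples per class), on the cleaned raw-restricted spectra,
once, shared across all preprocessing variants — so every variant is
scored on the identical test set.

## Synthetic data: what it emulates, and what it does not

Each spectrum is

    x(w) = m · [ Σ_b A_b g(w; c_b, σ_b) + offset + tilt·ŵ + drift(w) ] + ε(w)

with Gaussian band shapes g, six shared bands (4350–8400 cm⁻¹), two
class-sensitive bands at 7200 and 6400 cm⁻¹, multiplicative scatter
m ~ N(1, 0.05), baseline offset N(0.05, 0.02), a linear tilt, a smooth
random drift (16 random-amplitude, random-phase low-frequency cosines,
total sd 0.06 AU), and channel noise sd 5·10⁻⁴ AU, ×6 above 10000 cm⁻¹
(which is why that region is excluded before analysis). The grid is
4000–12000 cm⁻¹ at 8 cm⁻¹ (1001 channels); default class sizes 41/40/40.

Three generator choices are load-bearing:

* **Two class bands with non-proportional offsets.** With a single
  class-sensitive band the three class means are collinear in feature
  space, and no linear classifier can isolate the middle class under the
  nearest-to-1 rule — an instructive failure, but not the regime the
  workflow addresses. Offsets (0,0)/(0.05,0.012)/(0.10,0.045) AU keep the
  class triangle non-degenerate.
* **High-rank smooth drift.** The 16 random-phase cosines span ~32
  dimensions — more latent variables than the model may spend — so raw
  spectra stay imperfectly classifiable (~85–90 % test accuracy) while
  the second derivative, which attenuates a period-L cosine by
  (2π·σ_band/L)² ≪ 1, is essentially immune (~100 %). SNV (removing
  offset and scale but not drift shape) lands between. This reproduces
  the qualitative preprocessing ordering the workflow is built to
  demonstrate: derivative ≥ SNV > raw ≈ smoothing.
* **Gross injected outliers.** Orthogonal outliers add a 0.4 AU spurious
  band at 9000 cm⁻¹ (width 60 cm⁻¹); leverage points scale a spectrum
  ×5. The magnitudes are chosen to sit well above the within-class
  orthogonal residual floor (~0.8 AU under the default drift) — a
  "subtle" orthogonal outlier below that floor is undetectable in
  principle, since its energy adds in quadrature. Default contamination
  is 2–4 orthogonal outliers per class plus one leverage point, at the
  few-percent rate typical of real screens; every injection is recorded
  in the returned ground truth.

What the generator does *not* emulate: physical radiative transfer,
wavelength-dependent scatter coupling, instrument line-shape, or
non-Gaussian band shapes. Passing tests therefore demonstrate that the
pipeline recovers the right structure under a faithful statistical
caricature of NIR data, not that any particular real dataset would reach
the same accuracies.

## Numerical conventions

* SNV uses the n−1 (sample) standard deviation; constant spectra are an
  error naming the sample.
* Savitzky–Golay defaults: window 11 / order 2 (smoothing), window 15 /
  order 3 (second derivative); edges use scipy's one-sided polynomial
  fit. The derivative is taken per cm⁻¹ (units AU·cm²) and requires a
  uniform grid (relative spacing tolerance 10⁻⁶).
* NIPALS converges on the weight vector to 10⁻¹² (max 1000 iterations)
  and stops early with a warning if the X residual is exhausted.
* One global seed drives generation, projection directions, PRESS folds
  and MCCV resampling (child seeds are derived arithmetically), so a
  pipeline rerun is byte-identical.
* Problem sizes in the test-suite and acceptance script (121-sample
  sets, 100 MCCV splits, 5–20 seed replicates) are the package's default
  study conditions; the full suite runs in about a minute.

## Known limitations

* The robust screen's clean-data exclusion rate is conservative-biased
  (above nominal α) whenever within-class structure exceeds the fitted
  dimension; treat the flagged set as candidates for inspection, not as
  ground truth.
* PLS-DA is linear; class structures that are non-linearly separable
  (e.g. collinear class means) need a different decision rule.
* The F-test's dof convention treats pooled hold-out predictions as
  independent, which overstates n_pred; in practice the α = 0.25 default
  compensates by being deliberately permissive.
* No handling of wavelength misalignment between instruments; spectra
  are assumed on a common grid.
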