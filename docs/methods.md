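# Methods

This note documents the models and procedures implemented in `ftirclass`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data results do and do not show.

## Data model

Spectra are held as a wide matrix (samples × wavenumber points) on a shared
grid, canonically descending (4000 → 600 cm⁻¹, step 4, 851 points by
default — the acquisition range at 4 cm⁻¹ resolution; the true point
spacing of an instrument export is configurable).  Two intensity modes
exist: percent transmittance (%T, strictly positive) and absorbance
(A = 2 − log₁₀ %T).  Wavenumber intervals are closed: a grid point on a
boundary belongs to the interval.  Grids are strictly monotonic but not
necessarily uniform — excluding interior windows (water vapor
4000–3500 cm⁻¹, CO₂ 2442–2208 cm⁻¹) leaves gaps, which no downstream
algorithm depends on: the Savitzky–Golay derivative is taken with respect
to the point index (a constant factor on a uniform grid, absorbed by the
subsequent vector normalization), and area normalization integrates over
the actual wavenumber values.

## Pretreatment recipes

Eleven named recipes, each starting with the absorbance conversion:

| preset | chain |
|---|---|
| `none` | absorbance only ("raw") |
| `vector_first` / `vector_second` | SG derivative (window 9, order 2, deriv 1/2) → unit Euclidean norm |
| `minmax` / `area` | ATR correction → range-division / unit-area normalization |
| `ewma` | exponential smoothing, λ = 0.2 |
| `msc` | regression on the reference spectrum, de-slope/de-offset |
| `rc` | row centering |
| `sg` | SG smoothing only (window 9, order 2) |
| `snv` | per-row standardization (n−1 denominator) |
| `airpls` | baseline removal |

Open parameters fixed here: the SG polynomial order defaults to 2 (the
standard chemometrics choice; it must be < window); the EWMA constant
defaults to λ = 0.2 with a single forward pass; min–max normalization
defaults to dividing by (max − min) — the operation as the source study
words it — with the conventional (x − min)/(max − min) available behind a
flag; the `sg` recipe is smoothing-only, since derivatives appear only
inside the vector presets.  ATR correction uses the simple
penetration-depth model A′(ν) = A(ν)·ν/ν_ref (ν_ref = 1000 cm⁻¹): the ATR
effective path scales like 1/ν, and the vendor's exact correction is
proprietary; it is applied only inside the `minmax` and `area` presets.

**airPLS.**  Baselines are estimated per row by an iteratively reweighted
Whittaker smoother: minimize Σ wᵢ(xᵢ−zᵢ)² + λ‖D^d z‖², solved in banded
form.  After each iteration t, points above the baseline iterate (peak
candidates) get weight 0 and points below get wᵢ = exp(t·|dᵢ|/|d⁻|) with
d = x − z and |d⁻| the total negative deficit; iteration stops when
|d⁻| < tol·‖x‖₁.  Defaults λ = 10⁵, d = 2, max 15 iterations, tol = 10⁻³ —
the values of the algorithm's reference-implementation tradition, all
configurable.  On synthetic Gaussian peaks over a known linear baseline
the interior reconstruction error is ≲0.5 % of the baseline amplitude.

**Leakage control.**  A recipe can be *fitted* on the calibration set,
freezing any data-derived statistic (the MSC reference = calibration mean
spectrum); validation and external spectra are then transformed with the
frozen state.  The fitted recipe records how many rows it learned from,
which the tests use to verify that validation rows never enter
calibration statistics.

## Sample partitioning

Kennard–Stone selection: seed with the maximal-distance pair, then
repeatedly add the sample with the largest minimum Euclidean distance to
the selected set.  Ties break toward the lowest index, making the split
fully deterministic.  The split runs per class (stratified) by default so
both sets stay balanced — per-class metrics need positives and negatives
in each set — with the joint unstratified variant available.  Distances
are computed on the pretreatment under evaluation, matching the workflow
order (preprocess, then split).  The calibration quota is
round(fraction·n) per stratum, fraction 0.8 by default.

## Classifiers

**Random forest.**  A bagged ensemble of CART trees (scikit-learn
`DecisionTreeClassifier` does the tree fitting) with package-controlled
bootstrap bookkeeping: each tree trains on n draws with replacement and
the out-of-bag rows are retained, giving honest per-sample OOB vote
fractions without a holdout.  Tuning follows the OOB workflow: *n*\_tree is
chosen from {100, 200, 300, 500, 800, 1000} by lowest OOB
misclassification (tie → smaller); *m*\_try from 8 values in steps of 2
centered on floor(√p) (tie → higher calibration accuracy, then smaller).
Variable importance is OOB permutation accuracy importance — the mean drop
in a tree's OOB accuracy when a variable's OOB column is permuted —
rescaled to max = 1 so cutoff values are comparable across p (raw scores
are also exposed).  Only variables a tree actually splits on are permuted;
all others have exactly zero drop, which makes the computation fast
without approximation.  VIP selection keeps variables with rescaled
importance ≥ cutoff (padded to the top 2 if fewer survive), then the
forest is refit at the tuned (*n*\_tree, *m*\_try) on the selected columns.

**SVM.**  Soft-margin SVM with the RBF kernel K(x,y) = exp(−γ‖x−y‖²),
one-versus-one strategy.  When C and γ are unspecified they are selected
by 5-fold cross-validated accuracy over C ∈ {2⁻³…2⁷}, γ ∈ {2⁻¹⁰…2²}
(ties → smaller C, then smaller γ — determinism over optimism).  Scores
are logistic-squashed decision values oriented toward the positive class.

**PLS-DA.**  PLS1 regression (scikit-learn NIPALS, mean-centered,
columns unscaled — the chemometrics convention for spectra) on the class
coded {0, 1}; predict class 1 when ŷ ≥ 0.5.  The component count is chosen
by 5-fold CV misclassification (tie → fewer components), capped at 10 and
at the matrix rank.  Before fitting, calibration outliers are screened by
PCA (components to 95 % cumulative variance) and the Mahalanobis distance
of the scores against the χ²(k) 0.975 quantile.

All stochastic steps take explicit seeds (default 20220720).  Trained
models serialize to a directory — JSON metadata (kind, tuned parameters,
selected variable indices, importance) plus the fitted estimator via
joblib — and reload to bit-identical predictions.

## Evaluation

SENS, SPEC, ACC and MCC from the 2×2 table with the positive class = class
A by convention (the definitions need an orientation); a metric whose
denominator is zero is reported as 0 with a degeneracy flag rather than
raised, so grid experiments never abort.  AUC is the rank-based
Mann–Whitney statistic with midrank tie correction, computed on the
exposed scores (vote fraction / squashed decision value / ŷ) — equivalent
to the trapezoidal ROC area and invariant under monotone score transforms.
Calibration-set metrics are 5-fold CV predictions with the tuned
hyperparameters refit per fold, not resubstitution, which would be
trivially optimistic.

## Synthetic data

The generator emulates what the pretreatments exist to remove.  A clean
spectrum is a sum of Gaussian bands from a fixed catalogue — shared bands
at 3350, 2920, 2851, 1730, 1630, 1440, 1374, 1320, 1260, 1150, 1050 and
815 cm⁻¹, class-A-only bands at 1545, 1400, 930 cm⁻¹ and class-B-only
bands at 1528 and 781 cm⁻¹ — with per-sample log-normal amplitude jitter
(CV 0.1 by default).  Discriminating-band amplitudes sit at 13–23 % of the
strongest shared band so the problem is separable but not degenerate, and
band widths are chosen so every catalogued band is a resolvable local
maximum of the class-mean spectrum.  On top: a smooth baseline (degree-2
polynomial, coefficient SD 0.05 AU, positive offset, plus one broad random
hump), multiplicative/additive scatter distortion (y ← a·y + b,
a log-normal with σ = 0.08, b normal with σ = 0.01 AU) emulating
particle-size and thickness effects, and white noise (σ = 0.002 AU).
Absorbance is clipped to [0, 4] and emitted as %T = 10^(2−A).  One seeded
RNG stream per call with draws in fixed order makes output bit-identical
under (config, seed).

Fixtures: `easy` (the defaults, 100/class), `hard` (amplitude CV 0.6,
discriminating amplitudes ×0.25, noise σ 0.03, scatter σ 0.25 — class
distributions overlap), `noise_free` (every stochastic artifact off; any
sensible pipeline must reach ACC = 1), and `prescription` (easy training
set plus an external set with four extra shared "excipient" bands,
emulating compound formulations that dilute but preserve the herb
signature).

What passing tests show: the pipeline's arithmetic is correct against
independent oracles, the workflow is leakage-free and deterministic, and
under the generator's assumptions (additive Gaussian bands, smooth
baselines, affine scatter) the models recover the class structure.  What
they do not show: performance on real instrument data — real spectra have
Lorentzian/Voigt line shapes, correlated noise, water-vapor interference
structure and batch effects the generator does not model, so absolute
accuracies here do not transfer.

## Study workflow and problem sizes

`run_study` executes: load/generate → 11×3 pretreatment×classifier grid →
best cell by validation ACC (tie → MCC) → RF deep tuning on the best RF
recipe (*n*\_tree grid → *m*\_try grid → region experiment over the four
standard wavenumber windows → VIP-cutoff experiment over
{0.05, 0.01, 0.015, 0.020}) → final refit on the selected variables →
band report, tables, model bundle, and a manifest with per-file checksums.
SVM and PLS-DA stop at the grid stage; deep tuning is RF-only.  The
default study size — 200 spectra × 851 points — runs in well under ten
minutes on one CPU and is the size used throughout the tests and the
acceptance script.

## Known limitations

* The ATR correction is a first-order approximation; refractive-index
  inputs and vendor algorithms are out of scope.
* Binary classification only; the OVO machinery in the SVM is inherited
  but multiclass workflows are untested.
* JCAMP-DX reading covers the AFFN `(X++(Y..Y))` form only (no DIFDUP
  compression); writing JCAMP is out of scope.
* Importance localization is assessed on absorbance-scale spectra;
  derivative pretreatments deliberately relocate discriminative signal to
  band flanks, so selected wavenumbers then cluster beside, not on, the
  band centers.
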