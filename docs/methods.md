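# Methods

This note documents the models, estimators, default parameters and
numerical choices implemented in `selectiscreen`, and the scope of the
synthetic-data generators used to validate them.

## Variable-cluster reduction

Descriptors are standardized (zero mean, unit variance; columns with
variance ≤ `var_tol` = 1e-12 are dropped first) and clustered by
agglomerative hierarchical clustering with average linkage on the
distance 1 − |Pearson r|, cut to `k` clusters (default 30). For each
cluster the first principal component (via SVD, sign fixed so the
largest-magnitude loading is positive) serves as the cluster component.
Each variable's R²_own is its squared correlation with its own cluster
component; R²_next is the best squared correlation with any *other*
cluster's component. The representative of a cluster is the member with
the smallest ratio (1 − R²_own)/(1 − R²_next); ties break
lexicographically on the variable name. Guard: if the denominator is 0,
the ratio is 0 when the numerator is also ~0 (both correlations perfect)
and +∞ otherwise. An optional ANOVA-F prefilter (`prefilter_m` top
features) is available but disabled by default so that reduction is
purely unsupervised.

## Classifier benchmark

Eight families with these default hyperparameters (used when no grid is
searched): decision tree max_depth 10; k-NN k=5 with distance weighting;
SVM with RBF kernel, C=1; random forest and extremely randomized trees
with 200 trees, max_features 3; AdaBoost (depth-limited tree base
learner), gradient boosting and XGBoost with 200 estimators, depth 5.
Grid search maximizes mean accuracy over stratified 10-fold
cross-validation (shuffled with a fixed seed); ties keep the first
candidate in grid order. SVM probabilities come from
`CalibratedClassifierCV(SVC(), ensemble=False)` (sigmoid calibration on
the same folds), since decision-function-to-probability mapping is needed
for screening and AUC. XGBoost runs single-threaded (`n_jobs=1`) for
bit-reproducibility.

The metric suite (accuracy, sensitivity, specificity, precision, F1,
Cohen's κ, Matthews correlation) is computed directly from the confusion
matrix; any metric with an undefined denominator is reported as NaN with
the reason recorded rather than silently zeroed. AUC is the rank-based
Mann–Whitney statistic with ties counted ½. Models are ranked by TOPSIS:
criteria columns are vector-normalized, equally weighted, and closeness is
d⁻/(d⁺ + d⁻) to the per-criterion ideal/anti-ideal points; a single
alternative has closeness 1 by convention.

Library screening labels a compound active when its predicted
probability ≥ 0.5 (boundary inclusive, documented).

## Selectivity funnel

Compounds pass the target filter when target docking score < −8.5
kcal/mol and the selectivity filter when off-target score > −5.0 kcal/mol
(both strict; missing scores fail with the reason recorded in the
report's provenance). From the survivors, a seeded PAM-style k-medoids
(default 20 medoids) picks representatives, either on Euclidean distance
over descriptors or Tanimoto distance over binary fingerprints; when the
number of survivors is ≤ the requested count, all survivors are returned.

## Enzyme kinetics

* **Inhibition rate**: (control − sample)/control × 100.
* **IC50**: fractions p = inhibition/100 are clipped to (1e-4, 1−1e-4)
  and logit(p) is regressed on ln c, so logit(p) = b(ln c − ln IC50).
  The regression is weighted by (1 − p)²: percent-scale readings carry
  noise roughly proportional to the signal (constant coefficient of
  variation), and propagating var(y) = σ²y² through the logit transform
  gives var(logit p) = σ²/(1 − p)². Weights are re-estimated from the
  fitted curve (IRLS, ≤ 10 iterations). Standard errors come from the
  weighted-OLS covariance via the delta method. Curves that never cross
  50% are flagged `extrapolated`. A global nonlinear fit
  (`fit_kinetics_global`, scipy `curve_fit`) is provided as a
  cross-check.
* **Lineweaver–Burk**: OLS of 1/v on 1/[S] per inhibitor level gives
  slope Km_app/Vmax_app and intercept 1/Vmax_app.
* **Ki**: the LB slopes are regressed on [I]; Ki = intercept/gradient of
  that secondary line. A zero gradient yields the +∞ sentinel (no
  inhibition); a negative gradient is inconsistent with competitive
  inhibition and raises.
* **Mode classification** (tolerance 0.05 relative): competitive =
  constant Vmax with Km_app increasing as (1 + [I]/Ki); non-competitive =
  constant Km with decreasing Vmax; both varying = mixed; neither = none.
  Note that competitive inhibition *raises* the apparent Km — the
  standard result used throughout.
* **AUC of time courses**: trapezoidal rule on strictly increasing time
  grids (`numpy.trapezoid`).

## Fluorescence quenching

* **Stern–Volmer**: F0/F − 1 regressed on [Q] through the origin (F0 is
  the mean intensity at [Q] = 0); Ksv in L/mol. Kq = Ksv/τ0 with the
  fluorophore lifetime τ0 defaulting to 1.0×10⁻⁸ s, the standard
  biopolymer value; configurable.
* **Mechanism**: static iff Kq strictly exceeds the diffusion-limited
  bound 2.0×10¹⁰ L mol⁻¹ s⁻¹ (Kq exactly at the bound → dynamic).
  Ksv decreasing with temperature is reported as secondary supporting
  evidence only.
* **Binding**: log10((F0 − F)/F) regressed on log10[Q] by ordinary least
  squares; slope = n (site number), intercept = log10 Ka (Ka in L/mol,
  valid under static quenching). Points with F ≥ F0 at [Q] > 0 are
  excluded with a warning. For the 1:1 static model F = F0/(1 + Ka[Q])
  this recovers n = 1 and Ka = Ksv identically. The intercept is an
  extrapolation to [Q] = 1 mol/L, so Ka precision degrades when the
  quencher range sits far from unit concentration *and* quenching is
  weak (Ka·[Q] ≪ 1 throughout); the well-determined regime has
  appreciable quench across the titration.
* **van't Hoff**: log10 Ka regressed on 1/T; ΔH = −ln(10)·R·slope,
  ΔS = ln(10)·R·intercept with R = 8.314 J mol⁻¹ K⁻¹; ΔG(T) = ΔH − T·ΔS
  exactly for every reported temperature.
* **Synchronous spectra**: per-concentration peak wavelengths are refined
  by a three-point parabolic fit around the grid maximum; the reported
  quantities are the peak shift relative to [Q] = 0 (red shift =
  positive) and RSQF = 1 − F_peak/F0_peak.

## Synthetic-data generators

All generators use `numpy.random.default_rng` with explicit integer
seeds; identical seeds give byte-identical tables on any platform.

* **Descriptor matrix**: default 300 compounds × 1562 descriptors in
  three families (208 physicochemical, 163 taxonomy-style, 1191
  fingerprint bits, the last binarized). Columns come in pairs: 30 latent
  factors, 2 noisy copies each (noise SD 0.3), tiled across the
  requested width. Labels follow a sparse logistic model on the first 5
  factors (coefficient scale 2.0) and are then minimally repaired at the
  probability boundary to hit the exact design counts (default 151
  active / 149 inactive). The truth dict carries the factor partition,
  coefficients, labels and planted constants.
* **Docking scores**: per-target Gaussian mixtures (target:
  0.4·N(−9, 0.6) + 0.6·N(−6, 1.2); off-target analogous), with a designed
  5% of compounds drawn strictly inside both funnel cutoffs (target
  −8.8 − Exp(0.8); off-target −4.7 + U(0, 2.5)); the truth lists them.
* **Assays**: logistic dose–response (default IC50 23.03 µM, slope 1,
  8 doses log-spaced ±1.5 decades around IC50, multiplicative noise);
  competitive Michaelis–Menten rates (Km 2 mM, Vmax 1, Ki 0.5 mM);
  1:1 static quench F = F0/(1 + Ka(T)[Q]) with Ka(T) from ΔH = −30
  kJ/mol, ΔS = −50 J mol⁻¹ K⁻¹ at 300.15/305.15/310.15 K (noisy values
  clipped to stay ≤ F0, i.e. inside the quenching regime); Gaussian
  synchronous spectra with a planted 40% quench and +4 nm red shift.

These generators exist to validate the estimators against known truth;
they model the *structure* of each data type, not the chemistry of any
particular compound series.

## Limitations

* The benchmark's absolute performance numbers depend entirely on the
  synthetic label model; they demonstrate the pipeline, not real-world
  screening enrichment.
* The docking-score filters take scores as given; no docking is
  performed, and the kcal/mol cutoffs are fixed study conventions, not
  fitted thresholds.
* The IC50 and binding fits are linearized estimators chosen for
  robustness and transparency; for heteroscedastic real data beyond the
  constant-CV assumption, the global nonlinear fits should be preferred.
* The mechanism and mode classifiers are rule-based with fixed
  tolerances; borderline mixed-type inhibition or combined
  static/dynamic quenching is reported by the nearest rule, not by model
  selection.
* k-medoids representative picking is a seeded heuristic (PAM-style
  swaps); it is deterministic per seed but not globally optimal.
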