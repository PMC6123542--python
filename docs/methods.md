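# Methods

## Scope

`fibromet` implements the analysis chain of an NMR-metabolomics cohort
study — synthetic spectra with ground truth, spectral preprocessing,
metabolite quantification, supervised multivariate modelling, univariate
marker tables, and association analyses — as a library plus a thin CLI.
Wet-lab concerns (acquisition, phasing/baseline correction, metabolite
identification against spectral databases) are assumed done upstream and
are out of scope.

## Synthetic cohorts (`synthdata`)

**Forward model.** Each metabolite is a set of absorption-mode Lorentzian
singlets `(center δ, relative height h, half-width w)`.  A sample's
spectrum is

    S_i(δ) = d_i · Σ_m c_im · Σ_k h_mk · w²/((δ − δ_mk − ε_im)² + w²)
             + b_i(δ) + η_i(δ)

- **Concentrations** `c_im = 2^x`, `x ~ N(log₂β_m + Δ_gm, σ²)` with
  biological spread σ (`sigma_log2`, default **0.3**) — log-normal, so
  fold changes are positive and well defined.  Designed effects `Δ_gm`
  are log₂ fold changes against the reference (control) group; the
  packaged effect tables carry the published marker effects for the
  model-vs-control and three dose-vs-model contrasts.  Baseline
  concentrations β are arbitrary units (no absolute concentrations are
  available) and default to 1 for every metabolite.
- **Dilution** `d_i ~ U(0.5, 2)` by default, deliberately wide to
  exercise PQN.
- **Jitter** `ε_im ~ N(0, 0.002 ppm)` shifts all of a metabolite's peaks
  coherently per sample, making adaptive binning non-trivial.
- **Baseline drift**: per-sample quadratic with small random
  coefficients (sd **0.005** intensity units); **noise**: white Gaussian
  (sd **0.005**).  Both are small relative to peak heights (O(1)), as in
  well-phased CPMG spectra.
- **Axis**: 2,048 points over 0–10 ppm by default (fast, covers every
  packaged resonance); the full −5…15 ppm acquisition window at higher
  resolution is supported by passing another axis.
- **Line width**: uniform 0.003 ppm half-width (≈3 Hz at 500 MHz after
  exponential weighting).

**Packaged libraries.** The liver (39) and serum (28) metabolite panels
mirror the assigned resonances of typical CPMG spectra of liver extracts
and serum.  Peak positions are literature-style reference values, lightly
spaced so that every metabolite keeps at least one resolved resonance;
the matching assignment tables window exactly those resolved resonances,
the way an analyst picks integration regions.  Multiplet structure
(J-coupling), relaxation editing and lipoprotein/macromolecule humps are
not simulated.

**What passing tests show.** Recovery results on these cohorts
demonstrate that the pipeline is unbiased and correctly plumbed under
known ground truth with realistic nuisance (dilution, drift, jitter,
overlap).  They do not certify performance on real spectra, where peak
overlap is denser, lineshapes imperfect, and the assignment table itself
is uncertain.

## Preprocessing

Pipeline order is fixed: **excise → bin → PQN → Pareto**.

- **Water excision** removes δ 4.54–5.18 (closed interval) from the axis;
  the glucose α-anomeric resonance at δ 5.23 survives just outside it.
- **Adaptive binning**: boundaries at local minima of the cohort-mean
  spectrum.  A bin wider than `min_width` (0.01 ppm) is split at its
  deepest interior minimum when that minimum's depth below the smaller
  flanking maximum exceeds `min_prominence` (0.05) times that maximum;
  bins wider than `max_width` (0.12 ppm) are force-split into equal
  parts.  A noise floor — 5× the median absolute first difference of the
  mean spectrum — suppresses prominence splits in signal-free stretches;
  without it, quiet regions shatter into hundreds of noise slivers whose
  quotients would dominate the PQN median.  Bins never span excised
  gaps.  Integrals are trapezoidal with shared boundary points, so bin
  totals conserve the spectrum integral exactly.
- **PQN**: factor = median over features of sample/reference quotients;
  reference = feature-wise median over all samples (control-group median
  available).  Quotients use only signal-carrying features: reference
  values above 1% of the maximum reference value (non-positive references
  are always excluded).  Noise-floor bins do not carry dilution
  information — their integrals are baseline- and noise-dominated and can
  be negative — and would otherwise corrupt or even flip the median.
- **Pareto scaling**: mean-center, divide by √sd (n−1 denominator);
  zero-variance features are centered, divided by 1, and flagged.

**Known behavior worth knowing.** PQN assumes most features are
unchanged between groups.  In these synthetic cohorts *every* metabolite
carries a (possibly small) designed effect, so the per-sample factor
absorbs the bin-median group shift: near zero for the liver panel, about
+0.08 log₂ for the serum panel.  Recovered serum fold changes therefore
sit ~0.08–0.11 log₂ units below their designed values — a property of
median-quotient normalization under a fully perturbed panel, shared by
any faithful PQN, and well inside the ±0.15 recovery band used for
validation.  On real spectra, where unchanged background dominates, the
effect is smaller.

## Quantification

A metabolite's relative abundance is the weighted sum of PQN-normalized
bin integrals over its assignment windows; a bin belongs to a window when
its midpoint falls inside `[lo, hi)`.  Window edges extend up to
±0.063 ppm around the owned resonance, clipped to halfway toward the
nearest foreign resonance: since no bin is wider than 0.12 ppm, the bin
containing the resonance always has its midpoint inside the window, and
windows of different metabolites can never overlap.  STOCSY correlates
one driver feature against all features across samples (Pearson r and
covariance), supporting assignments: resonances of one molecule share a
concentration driver and correlate near 1.

## OPLS-DA

Classic O-PLS for a two-class response encoded −1/+1 and centered:
predictive weight `w ∝ X'y` (unit norm); per orthogonal component, the
current X-loading is orthogonalized against `w`, X is deflated by the
orthogonal score/loading outer product; the predictive component is
fitted on the deflated X.  Two identities hold by construction and are
tested: every orthogonal score has exactly zero sample correlation with
the encoded y, and deflation conserves ‖X‖².  Defaults: one orthogonal
component (2-D scores plots), Pareto scaling inside `fit` when requested.

- **R²Y** = 1 − residual y-variance after regression on the predictive
  score (training fit).
- **Q²Y** = 1 − PRESS/SS₀ under repeated (default 20) stratified two-fold
  CV, pooling squared out-of-fold errors of the encoded response;
  scaling is re-estimated inside each training fold.  Q² ≤ 0 means no
  predictive ability; Q² > R²Y is flagged, not fatal.
- **Permutation test**: the CV pipeline is re-run under uniformly
  permuted labels; p = (1 + #{Q²_perm ≥ Q²_obs}) / (1 + n_perm) — the
  add-one estimator, which cannot return 0.

Loadings are exported with each feature's correlation against the
predictive score (|r| is the blue-to-red color value of the classic
colored loadings plot).

## Univariate statistics

Per metabolite and contrast `(a, b)`: Shapiro–Wilk on each group at
`alpha_normality` = 0.05 gates a two-sided **Welch** t-test (chosen over
the pooled-variance form for safety under heteroscedasticity) versus the
Wilcoxon rank-sum test.  Effect = log₂ of the ratio of arithmetic group
means (geometric option available); non-positive means are flagged
rather than silently dropped.  Benjamini–Hochberg step-up runs per
contrast across metabolites; stars encode the adjusted q (*** < 0.001,
** < 0.01, * < 0.05) and both raw and adjusted values are reported.

## Associations

- **Ridge CCA**: both blocks standardized; covariance blocks shrunk as
  `C + ridge·I` (default ridge 0.1, since the metabolite count can
  approach the pooled sample count); canonical structure from the SVD of
  the whitened cross-covariance.  Correlations are clipped to [0, 1].
  For the correlation-circle biplot, per-variable correlations are taken
  against Gram-Schmidt-orthogonalized score pairs: the (r₁, r₂) point is
  then an R² decomposition and must lie inside the unit circle, which
  raw ridge variates (not exactly uncorrelated in-sample) would not
  guarantee.  At ridge = 0 the solution matches the classic generalized
  eigenproblem (tested against a brute-force oracle).
- **Correlation networks**: per group, pairwise Pearson r over that
  group's samples; edges kept at |r| ≥ threshold (default 0.6) with
  width |r| and sign attributes; nodes carry log₂FC and significance
  stars.  A curated reaction edge list (~40 pairs: purine degradation,
  TCA neighbors, choline derivatives, glutathione precursors, ketone
  bodies, one-carbon pool) can be overlaid as `kind="reaction"` edges;
  endpoints resolve case-insensitively through a synonym map, and the
  overlay never touches Pearson edges.  Graphs are `networkx`
  MultiGraphs (a pair may carry both a Pearson and a reaction edge) and
  export to GraphML/GML.

## Numerical choices and degenerate inputs

- Axis stored ascending; intervals half-open `[lo, hi)` except the
  closed excision interval.  Descending input files are reversed with
  pairing preserved.
- Standard deviations use the n−1 denominator throughout.
- All-zero spectra bin into one bin per retained segment; constant
  features are flagged (Pareto) or excluded with a warning (networks,
  CCA); a sample with no positive features is a named error in PQN.
- Matrix CSVs are written with shortest round-trip float formatting and
  read with round-trip parsing, so fixtures reproduce bit-exactly.
- Every stochastic routine takes an explicit seed; fixed seed ⇒
  bit-identical cohorts and byte-identical pipeline outputs.

## Validation problem sizes

Tests and the recovery script use 2-group cohorts of 15 samples/group on
the 2,048-point axis, 20–32 independent seeds for recovery means, 99
permutations for permutation-test checks, and 200 replicates for the
type-I-error calibration — sizes chosen so the full suite exercises every
claim at desk scale.

## Limitations

- No J-coupling, 2D experiments, relaxation editing, or instrument
  artifacts beyond baseline/noise/jitter; no peak fitting or
  deconvolution — quantification is window integration.
- The binning parameters of the original "adaptive, intelligent"
  algorithm are not recoverable; this implementation reproduces its
  intent (edges at signal valleys, no peak split across bins) with a
  documented, testable rule.
- Multi-class OPLS-DA, VIP scores, sparse/kernel variants, pathway
  enrichment and live database queries are out of scope.
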