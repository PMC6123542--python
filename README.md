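# fibromet

A ¹H-NMR metabolomics analysis pipeline for multi-group cohort studies of
liver fibrosis and its treatment, written for metabolomics analysts who
want the full chain — spectra to biomarker tables to networks — as
composable, tested Python.

The package covers the workflow used to characterize anti-fibrotic
mechanisms in a CCl₄ rodent model (control, fibrosis model, and three
treatment-dose groups; liver-extract and serum CPMG spectra at 500 MHz):

1. **Synthetic cohorts with ground truth** — Lorentzian forward model of
   the 39 liver / 28 serum assigned metabolites, per-metabolite group
   effects given as log₂ fold changes, log-normal biological spread,
   per-sample dilution factors, baseline drift, noise and chemical-shift
   jitter (`fibromet.synthdata`).
2. **Preprocessing** — water-region excision (δ 4.54–5.18), adaptive
   binning at local minima of the mean spectrum, probabilistic quotient
   normalization (PQN) and Pareto scaling (`fibromet.preprocess`-layer:
   `spectra`, `binning`, `normalize`).
3. **Quantification** — assignment-window integration into a
   sample × metabolite table, plus STOCSY profiles for assignment support
   (`fibromet.quantify`).
4. **Multivariate models** — two-class OPLS-DA with R²Y, repeated
   stratified two-fold cross-validated Q²Y and a label-permutation test
   (`fibromet.opls`).
5. **Univariate tables** — normality-gated Welch-t / rank-sum tests,
   log₂ fold changes, Benjamini–Hochberg FDR and star coding
   (`fibromet.stats`).
6. **Associations** — ridge-regularized canonical correlation (CCA)
   biplot tables and |r| ≥ 0.6 Pearson correlation networks with a curated
   biochemical-reaction overlay (`fibromet.associations`).

The fit/transform-shaped stages (`PQNNormalizer`, `ParetoScaler`,
`OPLSDA`, `RidgeCCA`) follow scikit-learn estimator conventions and
compose with sklearn pipelines and model selection.

## The model in brief

A sample's spectrum is simulated as

```
S_i(δ) = d_i · Σ_m c_im · Σ_k h_mk · L(δ − δ_mk − ε_im; w_mk) + b_i(δ) + η
```

with Lorentzian `L`, dilution `d_i ~ U(0.5, 2)`, concentrations
`log₂ c_im ~ N(log₂ β_m + Δ_gm, σ²)` where `Δ_gm` is the designed group
effect, shift jitter `ε_im` and polynomial baseline `b_i`.  PQN estimates
`d_i` as the median feature-wise quotient against a reference spectrum;
OPLS-DA splits the Pareto-scaled feature matrix into one y-predictive
component and orthogonal components with exactly zero sample correlation
to the encoded class; Q²Y = 1 − PRESS/SS₀ under repeated stratified 2-fold
CV, with significance from a permutation null using the add-one p-value
estimator.

## Worked example

```python
import fibromet as fm
from fibromet.pipeline import bins_pqn

library = fm.load_default_library("liver")           # 39 metabolites
effects = fm.load_default_effects("liver")           # per-contrast log2 FCs
design = fm.design_from_effects(effects, seed=1)     # control vs model, n=15
spectra, truth = fm.simulate_cohort(library, design)

trimmed = fm.excise_region(spectra, 4.54, 5.18)      # residual water
bins = fm.adaptive_bin(trimmed)
features, factors = fm.pqn_normalize(bins)
conc = fm.integrate_metabolites(bins_pqn(bins, factors),
                                fm.load_default_assignments("liver"))

table = fm.compare_groups(conc, spectra.annotations, ("model", "control"))
print(table.loc[["hypoxanthine", "lactate"], ["log2fc", "q_bh", "star"]])

y = spectra.annotations["group"].to_numpy()
q2 = fm.cross_validate_q2(conc.values.to_numpy(), y, repeats=20, seed=0)
print(f"Q2Y = {q2:.3f}")
```

Output:

```
                log2fc          q_bh star
metabolite
hypoxanthine -1.171987  1.903856e-09  ***
lactate       1.295443  1.462753e-07  ***
Q2Y = 0.934
```

The designed effects for this cohort were −1.11 (hypoxanthine) and +1.23
(lactate) log₂ units: the pipeline recovers them within the biological
spread of a 15-per-group design, flags both as highly significant after
FDR control, and the two groups cross-validate almost perfectly
(Q²Y ≈ 0.93).

The same chain runs end-to-end from a YAML config:

```bash
fibromet run --config src/fibromet/data/demo_config.yaml
```

which writes binned features, PQN factors, OPLS-DA scores/loadings per
contrast, fold-change tables for the four contrasts and one correlation
network per group, plus a manifest.

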