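# Methods

## Physical model

Steady-state photo-CIDNP enhancement of a proton arises from spin sorting
in a transient dye/target radical pair. For time-resolved experiments the
geminate polarization is proportional to
(1/12)|a_iso|²|g_D−g_M|μ_B B₀/ℏ divided by a radical-pair lifetime factor;
for steady-state work no closed-form prediction exists, which is why this
package treats the problem statistically. We keep the field- and
coupling-dependent core as the feature

    Q = (1/12) |a_iso|² |g_D − g_M| μ_B B₀ / ℏ   [rad³ s⁻³]

dropping the lifetime factor: under rapid diffusion beyond the exchange
region it is a site-independent prefactor. a_iso enters in MHz and is
converted to angular frequency internally; its sign is preserved for the
Kaptein bookkeeping but squared away in Q. Constants are CODATA values
from `scipy.constants`. Q is stored divided by 1e21 (recorded in table
metadata) so the feature sits near unity next to eV-scale energies.

The condensed nucleophilic Fukui index is the per-atom electron-density
change upon removal of one electron, f⁻_k = q_k(N−1) − q_k(N), condensed
onto heavy atoms. Per-proton values are read off the heavy atom bearing
the proton, with hydrogen charges folded into their bonded heavy atom —
the standard condensation convention; the underlying charge scheme
(Hirshfeld by default) is a free choice since the arithmetic is
scheme-agnostic. Validity requires Σf⁻ = 1 within 1e-6.

## Mechanism assignment

Hydroxyl-substituted aromatics may form their radical by electron
transfer (ET) or proton-coupled electron transfer (PCET); the two
radicals differ in g-factor and hyperfine pattern. For each candidate we
predict the net polarization phase per site with Kaptein's rule
Γ = μ·ε·sign(g_dye − g_radical)·sign(a_iso), defaulting to μ = +1
(triplet precursor, the usual case for xanthene dyes) and ε = +1
(polarization read on the regenerated diamagnetic molecule). Both signs
and the Δg orientation convention are configurable rather than
hard-coded, because phase bookkeeping conventions differ between
laboratories. The mechanism with the strictly larger fraction of
sign-matched sites wins; ties are reported as ambiguous and block feature
assembly, since a tie on real data indicates a data problem rather than a
coin to flip.

## Site ranking

The qualitative screening statistic is argmax concordance: per molecule,
does the site with the largest predictor value coincide with the largest
absolute-SNE site? Ties in either argmax count as flagged misses — a
predictor that cannot single out one site has not made a prediction. The
hit rate carries an exact Clopper–Pearson 95% interval. Absolute SNE is
used so emissive vs absorptive phase does not enter.

## Statistics

Features live at three hierarchy levels (logP per substituent family;
IP, N, gap, Δg per molecule; a_iso, f⁻, Q per proton), so trends are
fitted at matching coarse-grainings: all sites, max-SNE site per
molecule, or max-SNE row per (family, series). Trend fits are OLS with an
overall F-test; electron-transfer-related features (IP, N, LUMO–HOMO)
default to the quadratic form expected from Marcus theory's inverted
parabola, the rest to linear. Per-feature p-values are reported
unadjusted; Tukey HSD supplies the only multiplicity adjustment, in the
ANOVA stage (default design: features compared across low/medium/high
SNE classes).

PCA z-scores the eight features first (they span eV, MHz and
dimensionless indices, so correlation-matrix PCA is the only defensible
choice); zero-variance columns are dropped with a warning since they
cannot be scored. Explained-variance ratios are kept for all components
(they sum to 1) while scores and loadings are truncated to the requested
dimension.

## Machine learning

SNE classes are low (SNE < 40), medium (40–90) and high (> 90); boundary
values fall to medium, the symmetric closure of the two strict
inequalities. Because a single train/test split is dominated by where the
few high-SNE sites land, the classifier (multinomial logistic regression)
is refit over many stratified random splits — 10⁴ by default, enough for
sub-percent Monte-Carlo error on the diagonals, with the split count
config-reachable far higher — and all test predictions accumulate into
one row-normalized confusion matrix. Standardization is fit on the
training fold only. Importances are mean |standardized coefficient| per
feature, normalized. Splits default to 70/30 stratified; no class
weighting is applied by default, but both are configurable.

The regression suite is k-nearest-neighbors, gradient-boosted decision
trees (`GradientBoostingRegressor`; every report names the
implementation), random forest, ridge and RBF-SVR, each tuned on a
validation fold over a small fixed grid (documented in
`ml.MODEL_REGISTRY`) inside every one of the repeated 60/20/20 splits.
The composite performance score is the mean test-fold R², with RMSE and
MAE alongside; note that R² here is the coefficient of determination, so
a constant predictor scores 0 and predictions independent of the truth
score about −1. Importances are native impurity gain for tree models and
test-fold permutation importance (negative values floored at zero) for
the others, averaged over runs and normalized to sum 1.

## Synthetic library generator

The generator emulates the structure such a screening data set exhibits,
with defaults fixed at the study conditions: 27 indole, 5 amino-acid and
8 phenol derivatives (40 molecules, 3–7 proton sites each) measured at
B₀ = 14.1 T.

| parameter | default | meaning |
|---|---|---|
| fukui_dirichlet_alpha | 0.8 | per-molecule Dirichlet for f⁻ (sums to 1) |
| kappa, sigma_a | 90 MHz, 6 MHz | a_iso = κ·f⁻ + N(0, σ_a) |
| ip_mean, ip_sd | 7.5, 0.6 eV | molecule ionization potentials |
| ip_optimum, marcus_lambda | 7.3 eV, 0.6 eV⁻² | quadratic IP dependence of the SNE scale |
| delta_g_median, delta_g_sigma | 1.5e-3, 0.4 | lognormal Δg |
| gamma | 1.0 | Fukui exponent of the latent SNE |
| molecule_scale_sigma | 0.5 | lognormal molecule-to-molecule scale |
| sne_noise_sigma | 0.25 | multiplicative per-site noise |
| detection_floor | 1.0 | unobserved enhancements read as the floor |
| concordance | 0.925 | P(argmax SNE = argmax f⁻) per molecule |
| amino_series_attenuation | 0.25 | low-enhancement charged amino-indole series |

N is anticorrelated and the LUMO–HOMO gap positively correlated with IP
(weak donors have high IP, wide gap, low N); logP is drawn once per
(family, series) group. SNE noise is lognormal because SNE is a positive
ratio quantity. The within-molecule concordance is planted exactly: a
Bernoulli(concordance) draw per molecule decides whether the max-SNE site
is made to coincide with the max-Fukui site (swapping site SNE values
when needed), so argmax-recovery experiments are controlled binomial
trials rather than emergent properties of the noise settings.

`generate_class_structured` instead fixes the SNE class counts exactly
(default 143/40/7 low/medium/high on 190 sites, allocating leftover units
after flooring to the larger classes) and shifts feature means between
classes by a separation parameter in units of each feature's spread,
weighted toward logP, Δg and f⁻; separation 0 makes features
uninformative, 10 makes classes essentially separable.

What the generator does **not** emulate: real DFT feature distributions
and their mutual correlations beyond the few planted ones, spectral
overlap, phase information, relaxation during irradiation, or any
spin-dynamics beyond the Q formula. Passing tests therefore demonstrate
that the pipeline recovers planted structure at realistic sizes and noise
levels — not that any particular real library will behave the same way.

## Numerical choices and problem sizes

- One global integer seed; each stage derives a child seed by hashing the
  stage name, so stages are independent yet the whole run reproduces from
  the config alone. Fixed seeds give bit-identical tables and matrices.
- Feature CSVs are written at 17 significant digits and parsed with
  pandas' round-trip float parser, so write→read is exact for finite
  values.
- Default problem sizes in tests and the acceptance script — e.g. 500–2000
  replicate libraries for binomial recovery, 10⁴ classification splits,
  20-run regression suites — are chosen so each Monte-Carlo standard
  error is well below the tolerance being asserted.
- Degenerate inputs fail loudly: zero-variance predictors in trend fits,
  singleton ANOVA groups, unknown model names, negative fields, ambiguous
  mechanisms, infeasible class counts.

## Known limitations

- The dye's g-factor and LUMO energy default to plausible xanthene-dye
  values and must be set per dye in the config.
- The composite regression score is plain mean test R²; laboratories
  using weighted composites should post-process `per_run_scores`.
- The ET/PCET assignment uses only the net-effect rule; multiplet
  effects are out of scope.
- With only a handful of high-enhancement sites, the classifier's
  high-class diagonal has large sampling variance between libraries;
  conclusions about it should come from the cumulative matrix, never a
  single split.
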