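# cidnp-screen

Feature-based prediction of steady-state photo-CIDNP signal enhancement.

Photochemically induced dynamic nuclear polarization (photo-CIDNP) boosts
NMR sensitivity through light-driven radical-pair chemistry between a dye
and a target molecule, but there is no reliable theory for which proton of
which molecule will be enhanced in a steady-state experiment — candidates
are usually found by slow experimental screening. `cidnp-screen` is a
pipeline for the data-driven alternative: connect eight readily computable
molecular features of a compound library (indole, amino-acid and phenol
derivatives) to the measured per-proton signal-to-noise enhancement (SNE),
and use the resulting models to pre-screen new molecules *in silico*.

It is aimed at NMR spectroscopists and computational chemists who have
per-site feature tables (from DFT or cheminformatics tools) and measured
or hypothesized SNE values.

## What it computes

For every proton site the pipeline assembles eight features: ionization
potential *IP*, nucleophilicity index *N*, the E_LUMO(dye) − E_HOMO(target)
gap, the g-factor difference Δg = |g_D − g_M|, the isotropic hyperfine
coupling *a*_iso, the condensed nucleophilic Fukui index

&nbsp;&nbsp;&nbsp;&nbsp;*f*⁻_k = q_k(N−1) − q_k(N),

the geminate polarization probability

&nbsp;&nbsp;&nbsp;&nbsp;Q = (1/12) |a_iso|² |g_D − g_M| μ_B B₀ / ℏ,

and log*P*. On top of the table it runs:

- **Mechanism assignment** — Kaptein's net-effect sign rule
  Γ_net = μ · ε · sign(Δg) · sign(a_iso) applied to candidate ET
  (electron-transfer) and PCET (proton-coupled electron-transfer)
  radicals, choosing the mechanism whose predicted polarization phases
  best match observation.
- **Site ranking** — how often the site with the largest Fukui index is
  the site with the largest absolute SNE within a molecule, with exact
  binomial confidence intervals, and the same statistic for competing
  predictors (a_iso, Hirshfeld charge, spin density, Q).
- **Statistics** — three-level coarse-graining (site / molecule /
  family), linear and Marcus-like quadratic trend fits with F-test
  p-values, correlation-matrix PCA with loadings and cumulative explained
  variance, one-way ANOVA and Tukey HSD across SNE classes.
- **Machine learning** — a semiquantitative logistic classifier of
  low / medium / high enhancement (SNE < 40, 40–90, > 90) evaluated as a
  cumulative confusion matrix over thousands of random stratified splits,
  and a quantitative regression suite (k-NN, gradient-boosted trees,
  random forest, ridge, SVR) over repeated train/validation/test splits
  with averaged feature importances.
- **Simulation** — a synthetic library generator with planted ground
  truth (Fukui-dominant site effect, Marcus-like IP dependence,
  multiplicative noise, exact class counts), so the whole pipeline is
  testable without experimental data.

## Worked example

```bash
cidnp-screen --seed 11 --out demo simulate
cidnp-screen --seed 11 --out demo rank
cidnp-screen --seed 11 --out demo stats
cidnp-screen --seed 11 --out demo classify --runs 2000
```

prints

```
wrote 207 sites / 40 molecules to demo/feature_table.csv
fukui: 36/40 (rate 0.900)
a_iso: 34/40 (rate 0.850)
q_value: 34/40 (rate 0.850)
2-PC cumulative variance 0.710, 3-PC 0.849
diagonals: {'low': 0.9667..., 'medium': 0.1603..., 'high': 0.0917...}
```

Reading: in this simulated 40-molecule library the Fukui index picks the
most-enhanced proton in 36 of 40 molecules, beating the raw hyperfine
coupling (34/40); two principal components carry 71% of the feature
variance; and over 2000 random splits the logistic classifier recovers
low-enhancement sites reliably (97%) while medium/high sites — a handful
of rows in this particular random library — are hard, which is exactly
why the repeated-split protocol and its cumulative confusion matrix
matter at this data size. Separable synthetic classes drive all three
diagonals above 0.99 (see the test suite).

The same functions are importable directly:

```python
from cidnp_screen import GeneratorParams, generate_library, argmax_hit_rate
table, truth = generate_library(GeneratorParams(seed=0))
print(argmax_hit_rate(table, "fukui").hits)   # 37 of 40
```

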