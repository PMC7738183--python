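# granulekit

Quantitative analysis of insulin secretory-granule subpopulations.

Insulin-secreting β-cells carry two kinds of insulin granules distinguished
by their synaptotagmin calcium sensor: **syt7 granules** (high calcium
affinity, slow content release, smaller) and **syt9 granules** (low
affinity, fast release, larger).  Diabetes-model treatments delete one
subpopulation — palmitate (a lipotoxicity model) leaves only syt7 granules,
a pro-inflammatory cytokine cocktail leaves only syt9 granules — and the
loss shows up consistently in calcium dose-response curves, single-granule
release kinetics, granule sizes, lipid composition and stimulated
secretion.  `granulekit` implements the measurements that establish this
picture as a tested, reusable pipeline, together with seeded synthetic-data
generators (with ground truth) calibrated to the system's headline values,
so every analysis stage can be benchmarked end to end.

## What it computes

- **TIRF fusion photometry** (`granulekit.tirf`): granule detection on
  max-projections (median + k·MAD threshold, sub-pixel centroids), 5×5-px
  ROI photometry with annulus background subtraction, event segmentation,
  and a two-step content-release fit.  A release event is

  I(t) = I_dock, then I_dock·e^(−k_pore·(t−t_on)) during the pore phase,
  a step **ΔI_C** when the granule collapses into the bilayer, then
  (I_pre + ΔI_C)·e^(−k_post·(t−t_c)).

  ΔI_C measures the content still aboard at collapse; its bimodal
  distribution separates slow (syt7) from fast (syt9) release modes, which
  are labelled by a two-component Gaussian mixture.  Manders colocalization
  coefficients M1/M2 are included for two-channel images.
- **Calcium dose-response decomposition** (`granulekit.dose_response`):
  fraction-fused vs calcium fitted with a Hill mixture
  F(C) = F_max·Σⱼ wⱼ·C^h/(C^h + K_{1/2,j}^h), weighted by binomial
  variances, with AICc model selection between mono- and biphasic fits.
  The untreated mixture is biphasic (K_1/2 ≈ 10 and 48 µM); treatment
  scenarios collapse to one component.
- **FCS hydrodynamic sizing** (`granulekit.fcs`): autocorrelation fits of a
  one-state 3-D diffusion model with blinking (and optional triplet)
  corrections, G(τ) = 1 + (1/N)·X(τ)·B(τ)·T(τ); confocal-volume
  calibration from a reference dye; water viscosity from the Vogel equation
  η(T) = exp(A + B/(C+T)); and R_h = k_B·T/(6π·η(T)·D) per run before
  averaging.  Diameter lists are summarised and decomposed as Gaussian
  mixtures by EM.
- **Granule biochemistry statistics** (`granulekit.biochem`): lipidomics
  normalization (internal standard ÷ protein), syt9/syt7 volcano with
  Welch's t-test (−log₂ p axis), per-class enrichment, immunodepletion
  protein fractions, fractional and protein-normalized relative secretion,
  and ΔF/F calcium-trace normalization.
- **Synthetic data** (`granulekit.synthetic`): seeded generators for every
  input above — fusion outcomes, single-event traces, TIRF stacks (Poisson
  noise over Gaussian spots), FCS runs, diameter mixtures, lipid tables,
  depletion blots and KCl-stimulated secretion — with ground truth
  attached.
- **Orchestration** (`granulekit.pipeline`, CLI `granulekit`): end-to-end
  scenario runs with a YAML config, deterministic JSON reports and a
  config hash.

## Worked example

```sh
$ granulekit doseresponse --scenario untreated --seed 1 --granules 300 --out out/
{
 "scenario": "untreated",
 "n_components": 2,
 "k_half_um": [10.599, 49.357],
 "weights": [0.5285, 0.4715],
 ...
}
```

The simulated untreated granules are decomposed into a high-affinity
component (K_1/2 ≈ 10.6 µM, the syt7 subpopulation, true value 10) and a
low-affinity component (K_1/2 ≈ 49.4 µM, syt9, true value 48) carrying
roughly half the amplitude each — the biphasic signature of two coexisting
sensor types.

```sh
$ granulekit fcs --seed 1 --rh-nm 97
omega_r = 0.1993 um; diameter = 193.51 nm (Rh SD 0.96 nm, n=20)

$ granulekit sizes --scenario untreated --seed 3
untreated: 194.7 +/- 50.6 nm (n=2000)
mixture: means [177.2, 220.1] nm, weights [0.592, 0.408], separable=True
```

The FCS pipeline recovers the 97 nm input radius as a 193.5 nm diameter
after viscosity correction at each run's temperature, and the diameter
mixture splits the untreated sample into its smaller-syt7 / larger-syt9
components.

## Layout

```
src/granulekit/    synthetic, tirf, dose_response, fcs, biochem, pipeline, cli, io
tests/             unit + property tests, end-to-end recovery tests
docs/methods.md    models, calibrations, numerical choices, limitations
scripts/           acceptance.py
```
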