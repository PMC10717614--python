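# flimetab

Metabolic profiling of differentiating stem cells from two-photon
fluorescence lifetime imaging (2P-FLIM), as a tested, reusable Python
pipeline running entirely on synthetic data with known ground truth.

Human mesenchymal stromal cells switch from glycolysis towards
oxidative phosphorylation as they differentiate down the osteogenic
lineage. 2P-FLIM reads this shift out non-invasively: the NAD(P)H
fluorescence decay is a two-component mixture

    I(t) = I(0) [ α₁ e^(−t/τ₁) + α₂ e^(−t/τ₂) ] + C

whose long component τ₁ reports protein-bound NAD(P)H and whose
amplitude-weighted mean lifetime

    τ_avg = (τ₁α₁ + τ₂α₂) / (α₁ + α₂)

rises with OxPhos dependence, while the optical redox ratio
ORR = FAD⁺/NAD(P)H of the two intensity channels falls as the NAD(P)H
pool grows. The package provides:

* **`synthetic_data`** — forward simulation of every pipeline input:
  Poisson TCSPC decay histograms and decay-image stacks (80 MHz /
  12.5 ns window / 256 bins by default), NAD(P)H–FAD intensity pairs
  with prescribed ORR, colorimetric assay plates, qPCR Ct tables, and
  per-image feature tables at the measured time-course operating
  points; all seeded and carrying their ground truth.
* **`decay_fitting`** — bounded iteratively-reweighted least-squares
  fitting of the bi-exponential model on the decay tail, Neyman reduced
  χ² with the < 1.3 acceptance gate, and τ_avg.
* **`image_metrics`** — ROI segmentation (Otsu/percentile/fixed),
  ROI-aggregated decays, ratio-of-sums ORR, and per-image photonic
  feature vectors with explicit QC flags.
* **`assays`** — OLS standard curves, inverse regression with dilution
  factors, consumption Δ[metabolite] = [initial] − [final],
  exogenous-lactate correction, and alizarin-red-per-DNA
  mineralisation.
* **`expression`** — 2^(−ΔΔCt) fold changes against β-actin and a
  calibrator condition, per-gene z-score matrices, RNA-purity checks.
* **`multivariate`** — standardised PCA with 99% covariance error
  ellipses, pooled-covariance Mahalanobis distance, two-sample
  Hotelling's T² with F-value, critical F and p-value for every group
  pair, and a seeded UMAP wrapper.

## Worked example

Simulate a decay at the day-14 osteogenic operating point
(τ₁ = 3.146 ns, τ₂ = 0.400 ns, α₁ = 0.3336, 10⁶ photons), fit it, and
measure an ORR image pair at the lactate-supplemented operating point:

```python
import flimetab as fm

config = fm.AcquisitionConfig()                      # 80 MHz, 256 bins, 12.5 ns
truth = fm.DecayGroundTruth(tau1=3.146, tau2=0.400,
                            alpha1_frac=0.3336, total_photons=1e6)
fit = fm.fit_biexponential(fm.simulate_decay(truth, config, seed=14))
print(f"tau1 = {fit.tau1:.3f} ns  tau_avg = {fm.tau_avg(fit):.3f} ns  "
      f"chi2_red = {fit.chi2_reduced:.3f}  accepted = {fit.accepted}")

nadh, fad = fm.simulate_intensity_pair(0.547, 100.0, (128, 128), seed=3)
print(f"ORR = {fm.optical_redox_ratio(fad, nadh):.3f}")
```

prints

```
tau1 = 3.156 ns  tau_avg = 1.312 ns  chi2_red = 1.031  accepted = True
ORR = 0.545
```

— the fitted lifetimes recover the generating kinetics (true
τ_avg = 1.316 ns), the fit passes the χ² < 1.3 gate, and the redox
ratio lands on the prescribed 0.547 within Poisson error. Simulating
the full four-timepoint, two-condition experiment and testing group
separation in PCA space:

```python
tab = fm.simulate_feature_table(fm.OSTEO_TIMECOURSE, n_images=10, seed=0)
rep = fm.pairwise_group_report(
    tab[tab.day == 14],
    ["tau_avg", "tau1", "tau2", "alpha1_frac", "orr"])
print(rep[["group1", "group2", "mahalanobis", "f_value",
           "f_critical", "p_value", "significant"]].to_string(index=False))
```

```
group1 group2  mahalanobis    f_value  f_critical      p_value  significant
  Xpan Osteo+     8.102119 154.993561    3.591531 1.217041e-11         True
```

At day 14 the expansion- and osteogenic-medium clusters are separated
by >8 pooled standard deviations (F ≫ critical F, p ≪ 0.05); running
the same report at day 0 finds no significant separation — the
time-dependent metabolic divergence the imaging is designed to detect.

A `flimetab` console script exposes the same steps as subcommands
(`simulate`, `fit`, `features`, `assays`, `qpcr`, `cluster`); see
`flimetab --help`.

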