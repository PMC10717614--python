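# Methods

`flimetab` implements, end to end on synthetic data with known ground
truth, the quantitative analysis used to profile the metabolism of
differentiating human mesenchymal stromal cells (hMSCs) with two-photon
fluorescence lifetime imaging (2P-FLIM): TCSPC decay simulation and
bi-exponential fitting, lifetime and optical-redox-ratio metrics,
extracellular metabolite and qPCR arithmetic, and multivariate
cluster-separation statistics. This note records the models, the
parameters that matter, and the design choices made where the procedure
was genuinely open.

## Decay model and forward simulation

A TCSPC histogram records photon arrival times after each laser pulse.
With an 80 MHz source the acquisition window is the 12.5 ns pulse
period, split into 256 bins (bin width ~48.8 ps). The NAD(P)H decay is
modelled as a two-component exponential mixture plus a constant
background,

    I(t) = I(0) [ alpha1 exp(-t/tau1) + alpha2 exp(-t/tau2) ] + C,

with `tau1` the long (protein-bound) and `tau2` the short (free)
component. Internally the amplitudes are normalised fractions
(`alpha1 + alpha2 = 1`) with the overall scale carried separately;
this removes the scale degeneracy of the raw (alpha1, alpha2, I(0))
parameterisation.

The simulator computes each bin's expectation as the **exact integral**
of the mixture over the bin (not a midpoint sample), normalised so the
expected decay total over the window equals the requested photon
budget; window truncation is absorbed into the normalisation. Counts
are independent Poisson draws; background is a uniform per-bin Poisson
rate (default 0). No instrument response function is convolved in: the
decay starts at the peak bin, so the forward model is exactly the model
the fitter assumes and recovery tests isolate estimator behaviour
rather than IRF mismatch.

Every generator takes an integer seed (or an existing `numpy`
Generator) and is bit-reproducible; simulated objects carry their
ground-truth record.

## Fitting

Fits use the tail from the peak bin to the window end, with bounded
nonlinear least squares over (I0, alpha1, tau1, tau2, C). Defaults:
bounds tau1 in [1, 6] ns, tau2 in [0.1, 1] ns, alpha1 in [0, 1],
I0, C >= 0; starting values tau1 = 2.5 ns, tau2 = 0.4 ns,
alpha1 = 0.3, C = mean of the last five bins. These ranges are the
standard free/bound NAD(P)H lifetime ranges.

**Weighting.** A single weighted-least-squares pass with Neyman weights
1/max(obs, 1) — the traditional TCSPC choice — systematically
underweights upward-fluctuating low-count tail bins and biased the
recovered tau1 by about -1% at a typical operating point (1e5 photons,
tau1 = 2.8 ns). The default is therefore iteratively reweighted least
squares: a Neyman first pass followed by two passes with model-based
weights 1/max(mu, 1), the Gaussian approximation to Poisson maximum
likelihood. This cuts the bias to ~-0.35% without changing the
estimator's variance appreciably. `weighting="neyman"` restores the
single fixed-weight pass.

**Goodness of fit.** The acceptance statistic is the Neyman reduced
chi-squared, sum((obs-exp)^2 / max(obs, 1)) / (n_bins - 5), computed on
the fitted range. Fits are accepted iff they converged **and**
chi2_red < 1.3 (strict; the threshold is configurable). The statistic's
weighting scheme is stated here deliberately: chi-squared values under
other weightings are not comparable to this threshold. For correctly
specified fits at >= 1e5 photons the statistic is calibrated near 1 and
>= 95% of fits pass; a deliberately mono-exponential fit to strongly
bi-exponential data fails the gate essentially always.

**Canonicalisation.** Components are reported with tau1 >= tau2
regardless of initialisation; when the two lifetimes collapse within
1e-3 ns the fit is reported as effectively mono-exponential
(alpha1 = 1) to avoid label noise. Non-convergence sets
`converged=False` and `accepted=False`; it never raises.

The amplitude-weighted mean lifetime is
`tau_avg = (tau1*alpha1 + tau2*alpha2) / (alpha1 + alpha2)`; it always
lies between tau2 and tau1, and rises as metabolism shifts from
glycolysis towards oxidative phosphorylation.

## Image-level metrics

ROI analysis removes background before fitting. Default segmentation is
Otsu's threshold on the NAD(P)H intensity image (the channel with the
stronger cellular signal); percentile and fixed thresholds are
available. The same mask is applied to the FAD channel. The ROI decay
is the binwise sum of masked pixel decays — the primary fit target is
this aggregate, not per-pixel fits (per-pixel fitting exists behind the
CLI's `--per-pixel` flag). The optical redox ratio is the ratio of
summed masked FAD to summed masked NAD(P)H intensity. Ratio-of-sums
rather than mean-of-pixel-ratios is a real choice (the two differ); it
is robust to zero-count pixels and is named in the output metadata.

Images are flagged — never silently dropped — when segmentation finds
no foreground, when the ROI photon total falls below the configured QC
floor, or when the decay fit fails acceptance. The instrument-style QC
floor of 1e6 photons is interpreted as a floor on the total ROI photon
count; the `min_peak_photons` knob is exposed so a peak-bin
interpretation can be configured instead.

## Assay and expression arithmetic

Standard curves are ordinary least squares of reading against known
concentration (>= 3 distinct standards; a warning fires below
R^2 = 0.99). Concentrations are recovered by inverse regression times
the dilution factor; readings outside the calibrated response range are
flagged, not extrapolated. Consumption is
`delta = initial - final`, with initial medium concentrations of
1000 mg/L glucose and 2.0 mM glutamine (formulation values); lactate is
reported directly as secretion and, in lactate-supplemented media, is
corrected by subtracting the 7.5 mM exogenous supplement. Negative
deltas (net secretion) are flagged, and an observed zero consumption is
flagged distinctly from missing data. Units: glucose mg/L, lactate and
glutamine mM; the mg/dL -> mg/L conversion for glucose standards is
explicit. Mineralisation is alizarin-red absorbance per DNA
concentration from a PicoGreen curve (0-200 ng/mL range).

qPCR uses plain 2^-ddCt against a reference gene (default beta-actin)
and a calibrator condition, with technical replicates averaged
arithmetically before differencing (geometric averaging of Ct values
was rejected for transparency; Ct is already a log-scale quantity). No
amplification-efficiency correction is applied. Heatmap z-scores are
computed within gene across all samples jointly (not per timepoint),
with the sample (n-1) standard deviation — appropriate for small gene
panels — and zero-variance genes return flagged zero rows.
RNA-purity bookkeeping passes samples whose A260/A280 and A260/A230
ratios are within a configurable band (default +/- 0.2) of 1.8.

## Multivariate separation

Features are z-scored before PCA by default (nanosecond lifetimes and
photon-count intensities are incommensurate). PCA is deterministic up
to sign; signs are fixed so each component's largest-magnitude loading
is positive. Per-group 99% covariance error ellipses have semi-axes
sqrt(eigenvalue * chi2_2 quantile) along the covariance eigenvectors.

Group separation uses the classical equal-covariance two-sample
machinery: Mahalanobis distance D under the pooled covariance,
Hotelling's T^2 = n1*n2/(n1+n2) * D^2, and the exact F conversion
F = T^2 (n1+n2-p-1) / (p (n1+n2-2)) with (p, n1+n2-p-1) degrees of
freedom, reported with the critical F at alpha (default 0.05) and the
p-value. The pairwise report tests, by default, the first two PCA
scores — the space in which the ellipses are drawn — with a raw-feature
mode available; no multiple-testing correction is applied across pairs
(raw p-values are reported), matching the report-style output. UMAP is
a thin seeded wrapper over umap-learn (defaults n_neighbors=15,
min_dist=0.1, seed 42) and is never used for inference.

## What the synthetic data does and does not emulate

The generators reproduce the statistical structure the estimators care
about: Poisson photon noise at realistic budgets, exact
forward-model/fit-model agreement, affine plate chemistry with Gaussian
read noise, Ct tables whose noise-free ddCt analysis returns requested
folds exactly, and per-image feature tables drawn as independent
Gaussians at the measured condition x day operating points (means and
between-image SDs of tau_avg, tau1 and ORR for expansion and osteogenic
media over days 0/3/7/14, and for the three-condition day-14 lactate
comparison). They do **not** emulate instrument afterpulsing, dead
time, pile-up, IRF shape, spatial texture of real cells,
autofluorescence gradients, assay-chemistry nonlinearity, or
amplification-efficiency differences between primers. Passing tests
therefore demonstrate correctness of the estimators under the stated
models, not robustness to those instrument effects.

## Problem sizes and numerical choices

Simulation-based tests use 100-500 replicate histograms of 1e4-1e6
photons, 16x16- to 128-bin toy images for image-level checks, 2000
replicates for type-I-error calibration, and 1e4 points for ellipse
coverage — sizes chosen so the full suite completes in a couple of
minutes while keeping Monte-Carlo bands comfortably tighter than the
assertions. Degenerate inputs (all-zero histograms, uniform images,
empty masks, constant features, collinear scores, singular pooled
covariances) raise typed validation errors or return flagged results as
documented per function; optimiser non-convergence is always a flag,
never an exception.

## Known limitations

* Per-pixel lifetime fitting is functional but slow (one optimiser run
  per pixel) and is not the primary analysis path.
* The Hotelling machinery assumes equal group covariances; no
  Behrens-Fisher variant is provided.
* The chi-squared acceptance calibration is demonstrated at >= 1e5
  photons; at much lower counts the Neyman statistic drifts above 1 and
  the 1.3 gate becomes conservative.
* Fold-change uncertainty (replicate SD propagation through ddCt) is
  not computed; only point estimates are reported.
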