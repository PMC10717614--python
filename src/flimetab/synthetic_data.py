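"""Forward simulation of every input the analysis pipeline consumes.

All downstream stages (decay fitting, ROI metrics, assay arithmetic, qPCR
quantification, multivariate statistics) are exercised on synthetic data
with known ground truth.  This module generates:

* TCSPC decay histograms and decay-image stacks with Poisson photon noise
  from a bi-exponential kinetic ground truth (no IRF convolution — the
  forward model is exactly the model the fitter assumes, so recovery
  tests isolate estimator behaviour);
* NAD(P)H / FAD intensity-image pairs with a prescribed optical redox
  ratio;
* colorimetric microplate readings generated from an affine
  absorbance-concentration law with Gaussian read noise;
* qPCR Ct tables constructed so that noise-free delta-delta-Ct analysis
  returns requested fold changes exactly;
* grouped per-image photonic feature tables drawn around the measured
  operating points of the 14-day osteogenic-differentiation time course.

Every generator takes an integer ``seed`` and is bit-reproducible for
identical (parameters, seed).  Simulated objects carry their ground
truth for round-trip recovery testing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .decay_fitting import DecayHistogram

__all__ = [
    "AcquisitionConfig",
    "DecayGroundTruth",
    "FlimImage",
    "SimulationError",
    "simulate_decay",
    "expected_decay_counts",
    "simulate_flim_image",
    "simulate_intensity_pair",
    "simulate_assay_plate",
    "simulate_ct_table",
    "simulate_feature_table",
    "decay_truth_from_summary",
    "write_decay_stack",
    "read_decay_stack",
    "write_intensity_tiff",
    "read_intensity_tiff",
    "OSTEO_TIMECOURSE",
    "LACTATE_DAY14",
]


class SimulationError(ValueError):
    """Raised for invalid simulation parameters."""


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# acquisition geometry and kinetic ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionConfig:
    """TCSPC acquisition geometry.

    The default profile is an 80 MHz pulsed two-photon system: a 12.5 ns
    acquisition window split into 256 time bins, 512x512 pixel images,
    NAD(P)H excited at 760 nm and FAD at 800 nm, and a photon-count QC
    floor of 1e6 photons per ROI decay.
    """

    repetition_rate_mhz: float = 80.0
    n_bins: int = 256
    image_shape: tuple[int, int] = (512, 512)
    channels: tuple[str, ...] = ("NADPH", "FAD")
    excitation_nm: Mapping[str, float] = field(
        default_factory=lambda: {"NADPH": 760.0, "FAD": 800.0}
    )
    min_peak_photons: float = 1e6

    def __post_init__(self) -> None:
        if self.repetition_rate_mhz <= 0:
            raise SimulationError("repetition rate must be positive")
        if self.n_bins < 2:
            raise SimulationError("need at least 2 time bins")
        if len(self.image_shape) != 2 or min(self.image_shape) < 1:
            raise SimulationError("image_shape must be (rows, cols) with both >= 1")

    @property
    def window_ns(self) -> float:
        """Acquisition window = laser pulse period, 1000 / f[MHz] ns."""
        return 1000.0 / self.repetition_rate_mhz

    @property
    def bin_width_ns(self) -> float:
        return self.window_ns / self.n_bins

    def bin_edges(self) -> np.ndarray:
        return np.linspace(0.0, self.window_ns, self.n_bins + 1)

    def bin_centres(self) -> np.ndarray:
        edges = self.bin_edges()
        return 0.5 * (edges[:-1] + edges[1:])


@dataclass(frozen=True)
class DecayGroundTruth:
    """Kinetic parameters a simulated decay is drawn from.

    ``alpha1_frac`` is the normalised amplitude fraction of the long
    (protein-bound) component, tau1 > tau2 > 0 by convention.
    ``total_photons`` is the expected decay photon count over the window,
    excluding background; ``background_rate`` is a uniform Poisson rate
    in counts per bin.
    """

    tau1: float
    tau2: float
    alpha1_frac: float
    total_photons: float
    background_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (self.tau1 > self.tau2 > 0) and not (
            self.alpha1_frac == 1.0 and self.tau1 > 0
        ):
            raise SimulationError("require tau1 > tau2 > 0")
        if not 0.0 <= self.alpha1_frac <= 1.0:
            raise SimulationError("alpha1_frac must lie in [0, 1]")
        if self.total_photons <= 0:
            raise SimulationError("total_photons must be positive")
        if self.background_rate < 0:
            raise SimulationError("background_rate must be non-negative")


def decay_truth_from_summary(
    tau_avg: float,
    tau1: float,
    tau2: float = 0.4,
    total_photons: float = 1e5,
    background_rate: float = 0.0,
) -> DecayGroundTruth:
    """Invert the amplitude-weighted mean-lifetime formula for alpha1.

    Given a measured (tau_avg, tau1) operating point and the free-NAD(P)H
    lifetime tau2, solve tau_avg = a1*tau1 + (1-a1)*tau2 for the bound
    fraction a1.
    """
    if not tau2 <= tau_avg <= tau1:
        raise SimulationError("tau_avg must lie between tau2 and tau1")
    a1 = (tau_avg - tau2) / (tau1 - tau2)
    return DecayGroundTruth(
        tau1=tau1, tau2=tau2, alpha1_frac=a1,
        total_photons=total_photons, background_rate=background_rate,
    )


# ---------------------------------------------------------------------------
# decay histogram simulation
# ---------------------------------------------------------------------------

def _component_masses(tau: float, edges: np.ndarray) -> np.ndarray:
    """integral of exp(-t/tau) dt over each bin (units: ns)."""
    return tau * (np.exp(-edges[:-1] / tau) - np.exp(-edges[1:] / tau))


def expected_decay_counts(
    truth: DecayGroundTruth, config: AcquisitionConfig
) -> np.ndarray:
    """Noise-free expected counts per bin, background included.

    Per-bin expectations are the exact integral of the bi-exponential
    mixture over the bin (no midpoint sampling), normalised so that the
    expected decay total over the window (excluding background) equals
    ``truth.total_photons``; the window truncation is absorbed into the
    normalisation.
    """
    edges = config.bin_edges()
    m1 = truth.alpha1_frac * _component_masses(truth.tau1, edges)
    m2 = (1.0 - truth.alpha1_frac) * _component_masses(truth.tau2, edges)
    mix = m1 + m2
    lam = truth.total_photons * mix / mix.sum()
    return lam + truth.background_rate


def simulate_decay(
    truth: DecayGroundTruth,
    config: AcquisitionConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> DecayHistogram:
    """Draw one Poisson decay histogram from its kinetic ground truth."""
    config = config or AcquisitionConfig()
    rng = _rng(seed)
    lam = expected_decay_counts(truth, config)
    counts = rng.poisson(lam).astype(np.int64)
    return DecayHistogram(counts=counts, bin_edges=config.bin_edges())


# ---------------------------------------------------------------------------
# decay-image stacks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlimImage:
    """A simulated FLIM field of view for one channel.

    ``stack[r, c, k]`` holds photon counts in time bin ``k`` at pixel
    ``(r, c)`` (row-major, 0-based).  ``labels`` maps each pixel to the
    region whose :class:`DecayGroundTruth` it was drawn from; ``truths``
    records per-region ground truth for recovery testing.
    """

    stack: np.ndarray
    labels: np.ndarray
    truths: Mapping[int, DecayGroundTruth]
    bin_edges: np.ndarray
    channel: str = "NADPH"

    @property
    def intensity(self) -> np.ndarray:
        """Per-pixel total photon counts (time-summed stack, exactly)."""
        return self.stack.sum(axis=-1)


def simulate_flim_image(
    labels: np.ndarray,
    truths: Mapping[int, DecayGroundTruth],
    config: AcquisitionConfig | None = None,
    seed: int | np.random.Generator | None = None,
    channel: str = "NADPH",
) -> FlimImage:
    """Simulate a decay stack with region-wise kinetic ground truth.

    ``labels`` is an integer region map matching ``config.image_shape``;
    each label must have an entry in ``truths`` whose ``total_photons``
    is the expected per-pixel photon count (background regions are just
    regions with a dim truth).  Summing the returned stack over time
    reproduces the intensity image exactly, by construction.
    """
    config = config or AcquisitionConfig(image_shape=np.asarray(labels).shape)
    labels = np.asarray(labels)
    if labels.shape != tuple(config.image_shape):
        raise SimulationError(
            f"labels shape {labels.shape} != config.image_shape {config.image_shape}"
        )
    missing = set(np.unique(labels)) - set(truths)
    if missing:
        raise SimulationError(f"labels without ground truth: {sorted(missing)}")
    rng = _rng(seed)
    stack = np.zeros(labels.shape + (config.n_bins,), dtype=np.int64)
    for lab in sorted(np.unique(labels)):
        lam = expected_decay_counts(truths[int(lab)], config)
        idx = labels == lab
        stack[idx] = rng.poisson(lam, size=(int(idx.sum()), config.n_bins))
    return FlimImage(
        stack=stack, labels=labels, truths=dict(truths),
        bin_edges=config.bin_edges(), channel=channel,
    )


def simulate_intensity_pair(
    orr_true: float,
    nadh_mean: float,
    shape: tuple[int, int],
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate matched NAD(P)H / FAD intensity images inside one ROI.

    FAD pixels are Poisson with mean ``orr_true * nadh_mean`` so that the
    optical redox ratio FAD/NAD(P)H of the pair equals ``orr_true`` in
    expectation.
    """
    if orr_true < 0:
        raise SimulationError("orr_true must be non-negative")
    if nadh_mean <= 0:
        raise SimulationError("nadh_mean must be positive")
    rng = _rng(seed)
    nadh = rng.poisson(nadh_mean, size=shape).astype(np.int64)
    fad = rng.poisson(orr_true * nadh_mean, size=shape).astype(np.int64)
    return nadh, fad


# ---------------------------------------------------------------------------
# microplate assays
# ---------------------------------------------------------------------------

def simulate_assay_plate(
    true_concs: Sequence[float],
    slope: float,
    intercept: float,
    standard_concs: Sequence[float],
    noise_sd: float = 0.0,
    dilution: float = 1.0,
    analyte: str = "glucose",
    condition: str | None = None,
    day: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a colorimetric plate: standards plus diluted samples.

    Standards and samples obey the same affine absorbance law
    ``reading = intercept + slope * concentration_in_well`` with i.i.d.
    Gaussian read noise; samples are read after dilution by ``dilution``
    (so their in-well concentration is ``true_conc / dilution``).  The
    returned long-format table carries the ground-truth concentration of
    every well for round-trip testing.
    """
    standard_concs = np.asarray(standard_concs, dtype=float)
    if standard_concs.size == 0:
        raise SimulationError("at least one standard is required")
    true_concs = np.asarray(true_concs, dtype=float)
    if noise_sd < 0 or dilution <= 0:
        raise SimulationError("noise_sd must be >= 0 and dilution > 0")
    rng = _rng(seed)
    rows: list[dict] = []
    for i, conc in enumerate(standard_concs):
        reading = intercept + slope * conc + rng.normal(0.0, noise_sd)
        rows.append({
            "well": f"S{i + 1}", "role": "standard", "analyte": analyte,
            "reading": reading, "dilution": 1.0, "condition": condition,
            "day": day, "true_conc": conc,
        })
    for i, conc in enumerate(true_concs):
        reading = intercept + slope * conc / dilution + rng.normal(0.0, noise_sd)
        rows.append({
            "well": f"A{i + 1}", "role": "sample", "analyte": analyte,
            "reading": reading, "dilution": dilution, "condition": condition,
            "day": day, "true_conc": conc,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def simulate_ct_table(
    fold_changes: Mapping[str, float],
    ref_gene: str = "ACTB",
    calibrator: str = "Xpan",
    sample_condition: str = "Osteo+",
    calibrator_ref_ct: float = 20.0,
    sample_ref_ct: float = 21.0,
    calibrator_dcts: Mapping[str, float] | None = None,
    replicate_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Construct a long-format Ct table realising requested fold changes.

    For each gene the sample-condition Ct is placed so that exact
    delta-delta-Ct analysis of the noise-free table (reference gene
    ``ref_gene``, calibrator condition ``calibrator``) returns
    ``fold_changes[gene]``:  Ct_gene,sample = Ct_ref,sample + dCt_cal -
    log2(fold).  ``calibrator_dcts`` sets each gene's delta-Ct in the
    calibrator (default 6 cycles above the reference gene).
    """
    for gene, fold in fold_changes.items():
        if fold <= 0:
            raise SimulationError(f"fold change for {gene} must be positive")
    dcts = {g: 6.0 for g in fold_changes}
    if calibrator_dcts:
        dcts.update(calibrator_dcts)
    rng = _rng(seed)
    rows: list[dict] = []

    def add(condition: str, sample_id: str, gene: str, ct: float) -> None:
        for rep in range(1, n_replicates + 1):
            rows.append({
                "sample": sample_id, "condition": condition, "gene": gene,
                "ct": ct + rng.normal(0.0, replicate_sd), "replicate": rep,
            })

    add(calibrator, f"{calibrator}-1", ref_gene, calibrator_ref_ct)
    add(sample_condition, f"{sample_condition}-1", ref_gene, sample_ref_ct)
    for gene, fold in fold_changes.items():
        add(calibrator, f"{calibrator}-1", gene, calibrator_ref_ct + dcts[gene])
        add(sample_condition, f"{sample_condition}-1", gene,
            sample_ref_ct + dcts[gene] - np.log2(fold))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# grouped photonic feature tables (experiment operating points)
# ---------------------------------------------------------------------------

#: Measured NAD(P)H lifetime / redox operating points of the 14-day
#: osteogenic-differentiation time course, as (mean, SD) per condition and
#: day.  Expansion-medium (Xpan) cells are metabolically stable over the
#: course; osteogenic-medium (Osteo+) cells shift towards OxPhos (rising
#: tau_avg and tau1, falling ORR) from day 3 onward.  Day 0 is common to
#: both conditions.
OSTEO_TIMECOURSE: Mapping[str, Mapping[int, Mapping[str, tuple[float, float]]]] = {
    "Xpan": {
        0: {"tau_avg": (1.097, 0.040), "tau1": (2.683, 0.027), "orr": (0.724, 0.020)},
        3: {"tau_avg": (1.097, 0.040), "tau1": (2.683, 0.027), "orr": (0.724, 0.020)},
        7: {"tau_avg": (1.097, 0.040), "tau1": (2.683, 0.027), "orr": (0.724, 0.020)},
        14: {"tau_avg": (1.097, 0.040), "tau1": (2.683, 0.027), "orr": (0.724, 0.020)},
    },
    "Osteo+": {
        0: {"tau_avg": (1.097, 0.040), "tau1": (2.683, 0.027), "orr": (0.724, 0.020)},
        3: {"tau_avg": (1.167, 0.004), "tau1": (2.800, 0.039), "orr": (0.615, 0.021)},
        7: {"tau_avg": (1.236, 0.010), "tau1": (2.979, 0.053), "orr": (0.534, 0.029)},
        14: {"tau_avg": (1.316, 0.011), "tau1": (3.146, 0.015), "orr": (0.585, 0.012)},
    },
}

#: Day-14 operating points of the lactate-supplementation comparison
#: (expansion, osteogenic, and lactate-supplemented osteogenic medium).
LACTATE_DAY14: Mapping[str, Mapping[str, tuple[float, float]]] = {
    "Xpan": {"tau_avg": (1.108, 0.002), "orr": (0.779, 0.016)},
    "Osteo+": {"tau_avg": (1.187, 0.014), "orr": (0.668, 0.011)},
    "Osteo+Lact": {"tau_avg": (1.148, 0.005), "orr": (0.547, 0.016)},
}

#: free-NAD(P)H lifetime used when converting (tau_avg, tau1) operating
#: points to amplitude fractions, and its between-image SD
TAU2_OPERATING = (0.400, 0.010)

#: per-image mean NAD(P)H pixel intensity (counts) and its relative SD
NADPH_INTENSITY_OPERATING = (5.0e4, 0.05)


def simulate_feature_table(
    scenario: Mapping = OSTEO_TIMECOURSE,
    n_images: int = 10,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw a per-image photonic feature table around measured group means.

    Each row is one image: lifetime metrics and intensities drawn as
    independent Gaussians at the (mean, SD) operating point of its
    condition x day cell; derived columns (``alpha1_frac``,
    ``fad_intensity``) are computed from the drawn values so that the
    feature-vector identities (tau_avg = a1*tau1 + (1-a1)*tau2,
    orr = fad/nadph) hold exactly per row.

    ``scenario`` is either {condition: {day: {metric: (mean, sd)}}} or
    the flat single-day form {condition: {metric: (mean, sd)}}.
    """
    if n_images < 1:
        raise SimulationError("n_images must be >= 1")
    rng = _rng(seed)
    first = next(iter(scenario.values()))
    nested = isinstance(next(iter(first.values())), Mapping)
    flat: list[tuple[str, int | None, Mapping]] = []
    if nested:
        for cond, days in scenario.items():
            for day, point in days.items():
                flat.append((cond, day, point))
    else:
        flat = [(cond, None, point) for cond, point in scenario.items()]

    rows: list[dict] = []
    for cond, day, point in flat:
        for i in range(n_images):
            t1 = rng.normal(*point["tau1"]) if "tau1" in point else np.nan
            t2 = rng.normal(*TAU2_OPERATING)
            tavg = rng.normal(*point["tau_avg"])
            orr = rng.normal(*point["orr"])
            nadph = rng.normal(
                NADPH_INTENSITY_OPERATING[0],
                NADPH_INTENSITY_OPERATING[0] * NADPH_INTENSITY_OPERATING[1],
            )
            a1 = (tavg - t2) / (t1 - t2) if np.isfinite(t1) else np.nan
            rows.append({
                "image_id": f"{cond}-d{day}-{i}", "group": cond, "day": day,
                "tau_avg": tavg, "tau1": t1, "tau2": t2, "alpha1_frac": a1,
                "nadph_intensity": nadph, "fad_intensity": orr * nadph,
                "orr": orr,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# container I/O
# ---------------------------------------------------------------------------

def write_decay_stack(path, image: FlimImage) -> None:
    """Write a decay stack to an HDF5 container.

    Layout: datasets ``counts[rows, cols, bins]`` (chunked by row),
    ``labels[rows, cols]``, ``bin_edges`` (ns); attribute ``channel``;
    group ``truth/<label>`` with the ground-truth kinetic parameters as
    attributes.
    """
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset(
            "counts", data=image.stack,
            chunks=(1, image.stack.shape[1], image.stack.shape[2]),
        )
        f.create_dataset("labels", data=image.labels)
        f.create_dataset("bin_edges", data=image.bin_edges)
        f.attrs["channel"] = image.channel
        grp = f.create_group("truth")
        for lab, t in image.truths.items():
            g = grp.create_group(str(lab))
            for k, v in dataclasses.asdict(t).items():
                g.attrs[k] = v


def read_decay_stack(path) -> FlimImage:
    """Read a decay stack written by :func:`write_decay_stack`."""
    import h5py

    with h5py.File(path, "r") as f:
        truths = {
            int(lab): DecayGroundTruth(**dict(g.attrs))
            for lab, g in f["truth"].items()
        }
        return FlimImage(
            stack=f["counts"][()], labels=f["labels"][()],
            truths=truths, bin_edges=f["bin_edges"][()],
            channel=str(f.attrs["channel"]),
        )


def write_intensity_tiff(path, image: np.ndarray) -> None:
    """Write an intensity image as 16-bit single-channel TIFF."""
    import tifffile

    arr = np.asarray(image)
    if arr.min() < 0 or arr.max() > np.iinfo(np.uint16).max:
        raise SimulationError("intensity image does not fit in uint16")
    tifffile.imwrite(path, arr.astype(np.uint16))


def read_intensity_tiff(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)
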