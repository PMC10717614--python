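import numpy as np
import pytest

from flimetab import AcquisitionConfig, DecayGroundTruth


@pytest.fixture(scope="session")
def default_config() -> AcquisitionConfig:
    """80 MHz / 256-bin / 512x512 acquisition profile."""
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def small_config() -> AcquisitionConfig:
    """Toy acquisition for image-level tests: 16x16 pixels, 128 bins."""
    return AcquisitionConfig(image_shape=(16, 16), n_bins=128)


@pytest.fixture(scope="session")
def reference_truth() -> DecayGroundTruth:
    """A typical NAD(P)H operating point used across fitting tests."""
    return DecayGroundTruth(
        tau1=3.0, tau2=0.4, alpha1_frac=0.3, total_photons=1e5
    )


def truncated_mixture_mean(truth: DecayGroundTruth, window: float) -> float:
    """Independent closed form: mean arrival time of the window-truncated
    bi-exponential mixture.

    Component photon weights are proportional to a_i * tau_i * (1 -
    exp(-T/tau_i)); each truncated exponential has conditional mean
    tau - T*exp(-T/tau)/(1 - exp(-T/tau)).
    """
    comps = [
        (truth.alpha1_frac, truth.tau1),
        (1.0 - truth.alpha1_frac, truth.tau2),
    ]
    weights, means = [], []
    for a, tau in comps:
        trunc = 1.0 - np.exp(-window / tau)
        weights.append(a * tau * trunc)
        means.append(tau - window * np.exp(-window / tau) / trunc)
    weights = np.asarray(weights) / np.sum(weights)
    return float(np.dot(weights, means))
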