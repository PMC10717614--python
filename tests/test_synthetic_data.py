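"""The forward simulators: geometry, Poisson statistics, reproducibility."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import flimetab as fm
from flimetab import (
    AcquisitionConfig,
    DecayGroundTruth,
    SimulationError,
    expected_decay_counts,
    simulate_assay_plate,
    simulate_ct_table,
    simulate_decay,
    simulate_feature_table,
    simulate_flim_image,
    simulate_intensity_pair,
)

from conftest import truncated_mixture_mean


class TestAcquisitionConfig:
    def test_default_profile_is_80mhz_256bin(self, default_config):
        assert default_config.window_ns == pytest.approx(12.5)
        assert default_config.n_bins == 256
        assert default_config.image_shape == (512, 512)
        assert default_config.min_peak_photons == 1e6
        assert default_config.bin_width_ns == pytest.approx(12.5 / 256)

    def test_bin_edges_span_window_exactly(self, default_config):
        edges = default_config.bin_edges()
        assert edges.shape == (257,)
        assert edges[0] == 0.0
        assert edges[-1] == pytest.approx(12.5)

    @pytest.mark.parametrize(
        "kwargs",
        [{"repetition_rate_mhz": 0.0}, {"n_bins": 1}, {"image_shape": (0, 4)}],
    )
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(SimulationError):
            AcquisitionConfig(**kwargs)


class TestDecaySimulation:
    def test_histogram_has_256_bins_over_12p5_ns(
        self, reference_truth, default_config
    ):
        hist = simulate_decay(reference_truth, default_config, seed=0)
        assert hist.n_bins == 256
        assert hist.bin_edges[-1] - hist.bin_edges[0] == pytest.approx(12.5)

    def test_mean_arrival_matches_truncated_mixture_closed_form(
        self, default_config
    ):
        truth = DecayGroundTruth(
            tau1=3.0, tau2=0.4, alpha1_frac=0.3, total_photons=1e6
        )
        hist = simulate_decay(truth, default_config, seed=7)
        t = hist.bin_centres
        emp_mean = float(np.sum(t * hist.counts) / hist.counts.sum())
        analytic = truncated_mixture_mean(truth, default_config.window_ns)
        emp_var = float(
            np.sum(hist.counts * (t - emp_mean) ** 2) / hist.counts.sum()
        )
        se = np.sqrt(emp_var / hist.counts.sum())
        assert abs(emp_mean - analytic) < 3 * se

    def test_mono_exponential_log_expectation_is_affine(self, default_config):
        truth = DecayGroundTruth(
            tau1=2.5, tau2=0.4, alpha1_frac=1.0, total_photons=1e5
        )
        lam = expected_decay_counts(truth, default_config)
        slopes = np.diff(np.log(lam)) / default_config.bin_width_ns
        np.testing.assert_allclose(slopes, -1.0 / 2.5, rtol=1e-9)

    def test_expected_total_matches_requested_photons(
        self, reference_truth, default_config
    ):
        lam = expected_decay_counts(reference_truth, default_config)
        assert lam.sum() == pytest.approx(reference_truth.total_photons)

    def test_background_adds_uniform_rate(self, default_config):
        base = DecayGroundTruth(
            tau1=3.0, tau2=0.4, alpha1_frac=0.3, total_photons=1e4
        )
        with_bg = DecayGroundTruth(
            tau1=3.0, tau2=0.4, alpha1_frac=0.3, total_photons=1e4,
            background_rate=2.5,
        )
        np.testing.assert_allclose(
            expected_decay_counts(with_bg, default_config)
            - expected_decay_counts(base, default_config),
            2.5,
        )

    def test_poisson_dispersion_index_near_one(self, default_config):
        truth = DecayGroundTruth(
            tau1=3.0, tau2=0.4, alpha1_frac=0.3, total_photons=2e4
        )
        rng = np.random.default_rng(11)
        reps = np.stack(
            [simulate_decay(truth, default_config, seed=rng).counts
             for _ in range(500)]
        )
        mean = reps.mean(axis=0)
        var = reps.var(axis=0, ddof=1)
        informative = mean >= 5
        dispersion = var[informative] / mean[informative]
        assert informative.sum() > 100
        assert dispersion.mean() == pytest.approx(1.0, abs=0.05)

    def test_same_seed_bit_identical(self, reference_truth, default_config):
        a = simulate_decay(reference_truth, default_config, seed=42)
        b = simulate_decay(reference_truth, default_config, seed=42)
        assert np.array_equal(a.counts, b.counts)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"tau1": 0.4, "tau2": 3.0, "alpha1_frac": 0.3, "total_photons": 1e4},
            {"tau1": 3.0, "tau2": 0.4, "alpha1_frac": 1.5, "total_photons": 1e4},
            {"tau1": 3.0, "tau2": 0.4, "alpha1_frac": 0.3, "total_photons": 0},
        ],
    )
    def test_invalid_truth_rejected(self, kwargs):
        with pytest.raises(SimulationError):
            DecayGroundTruth(**kwargs)


class TestFlimImage:
    def test_time_sum_equals_intensity_exactly(self, small_config):
        labels = np.zeros(small_config.image_shape, dtype=int)
        labels[4:12, 4:12] = 1
        truths = {
            0: DecayGroundTruth(tau1=3.0, tau2=0.4, alpha1_frac=0.3,
                                total_photons=2.0),
            1: DecayGroundTruth(tau1=3.0, tau2=0.4, alpha1_frac=0.3,
                                total_photons=200.0),
        }
        img = simulate_flim_image(labels, truths, small_config, seed=3)
        np.testing.assert_array_equal(img.stack.sum(axis=-1), img.intensity)

    def test_shape_mismatch_rejected(self, small_config):
        labels = np.zeros((8, 8), dtype=int)
        truths = {0: DecayGroundTruth(tau1=3.0, tau2=0.4, alpha1_frac=0.3,
                                      total_photons=10.0)}
        with pytest.raises(SimulationError):
            simulate_flim_image(labels, truths, small_config, seed=0)

    def test_missing_truth_for_label_rejected(self, small_config):
        labels = np.zeros(small_config.image_shape, dtype=int)
        labels[0, 0] = 7
        truths = {0: DecayGroundTruth(tau1=3.0, tau2=0.4, alpha1_frac=0.3,
                                      total_photons=10.0)}
        with pytest.raises(SimulationError):
            simulate_flim_image(labels, truths, small_config, seed=0)

    def test_same_seed_bit_identical(self, small_config):
        labels = np.zeros(small_config.image_shape, dtype=int)
        labels[2:10, 2:10] = 1
        truths = {
            0: DecayGroundTruth(tau1=3.0, tau2=0.4, alpha1_frac=0.3,
                                total_photons=2.0),
            1: DecayGroundTruth(tau1=2.8, tau2=0.45, alpha1_frac=0.3,
                                total_photons=100.0),
        }
        a = simulate_flim_image(labels, truths, small_config, seed=9)
        b = simulate_flim_image(labels, truths, small_config, seed=9)
        assert np.array_equal(a.stack, b.stack)

    def test_container_round_trip(self, small_config, tmp_path):
        labels = np.zeros(small_config.image_shape, dtype=int)
        labels[2:10, 2:10] = 1
        truths = {
            0: DecayGroundTruth(tau1=3.0, tau2=0.4, alpha1_frac=0.3,
                                total_photons=2.0),
            1: DecayGroundTruth(tau1=2.8, tau2=0.45, alpha1_frac=0.3,
                                total_photons=100.0),
        }
        img = simulate_flim_image(labels, truths, small_config, seed=9)
        path = tmp_path / "stack.h5"
        fm.write_decay_stack(path, img)
        back = fm.read_decay_stack(path)
        assert np.array_equal(back.stack, img.stack)
        assert np.array_equal(back.labels, img.labels)
        assert back.truths[1].tau1 == pytest.approx(2.8)

    def test_intensity_tiff_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        image = rng.poisson(100, size=(16, 16))
        path = tmp_path / "intensity.tif"
        fm.write_intensity_tiff(path, image)
        np.testing.assert_array_equal(fm.read_intensity_tiff(path), image)


class TestIntensityPair:
    def test_unit_ratio_recovered_at_high_photons(self):
        nadh, fad = simulate_intensity_pair(1.0, 5000.0, (64, 64), seed=1)
        assert fad.sum() / nadh.sum() == pytest.approx(1.0, abs=0.01)

    def test_fad_mean_scales_with_orr(self):
        nadh, fad = simulate_intensity_pair(0.5, 1000.0, (128, 128), seed=2)
        assert fad.mean() == pytest.approx(500.0, rel=0.02)

    def test_negative_inputs_rejected(self):
        with pytest.raises(SimulationError):
            simulate_intensity_pair(-0.1, 100.0, (8, 8), seed=0)
        with pytest.raises(SimulationError):
            simulate_intensity_pair(0.5, 0.0, (8, 8), seed=0)


class TestAssayPlate:
    def test_zero_noise_round_trip_is_identity(self):
        true_concs = [50.0, 120.0, 260.0]
        plate = simulate_assay_plate(
            true_concs, slope=0.002, intercept=0.01,
            standard_concs=np.linspace(0.0, 300.0, 8), noise_sd=0.0,
            dilution=1.0, seed=0,
        )
        curve = fm.fit_standard_curve(plate[plate.role == "standard"])
        samples = plate[plate.role == "sample"]
        recovered = [
            fm.reading_to_concentration(curve, r.reading, r.dilution)
            for r in samples.itertuples()
        ]
        np.testing.assert_allclose(recovered, true_concs, rtol=1e-9)

    def test_blank_samples_recover_zero(self):
        plate = simulate_assay_plate(
            [0.0, 0.0], slope=0.002, intercept=0.01,
            standard_concs=np.linspace(0.0, 300.0, 8), noise_sd=0.0, seed=0,
        )
        curve = fm.fit_standard_curve(plate[plate.role == "standard"])
        for r in plate[plate.role == "sample"].itertuples():
            assert fm.reading_to_concentration(curve, r.reading, r.dilution) \
                == pytest.approx(0.0, abs=1e-9)

    def test_fitted_slope_within_3se_of_truth(self):
        # OLS sampling distribution: SE(slope) = sigma / sqrt(Sxx)
        slope, sigma = 0.002, 0.004
        standards = np.linspace(0.0, 300.0, 8)
        sxx = np.sum((standards - standards.mean()) ** 2)
        se = sigma / np.sqrt(sxx)
        rng = np.random.default_rng(5)
        slopes = []
        for _ in range(200):
            plate = simulate_assay_plate(
                [], slope=slope, intercept=0.01, standard_concs=standards,
                noise_sd=sigma, seed=rng,
            )
            slopes.append(
                fm.fit_standard_curve(plate[plate.role == "standard"]).slope
            )
        assert abs(np.mean(slopes) - slope) < 3 * se / np.sqrt(200)

    def test_empty_standards_rejected(self):
        with pytest.raises(SimulationError):
            simulate_assay_plate([1.0], 0.002, 0.01, standard_concs=[], seed=0)


class TestCtTable:
    def test_zero_noise_round_trip_reproduces_folds(self):
        folds = {"ALPL": 2.3, "SPP1": 15.47, "RUNX2": 1.0}
        table = simulate_ct_table(folds, replicate_sd=0.0, seed=0)
        result = fm.delta_delta_ct(table, ref_gene="ACTB", calibrator="Xpan")
        sample = result[result.condition == "Osteo+"].set_index("gene")
        for gene, fold in folds.items():
            assert sample.loc[gene, "fold"] == pytest.approx(fold, abs=1e-9)

    def test_unit_fold_means_matching_dcts(self):
        table = simulate_ct_table({"GAPDH": 1.0}, replicate_sd=0.0, seed=0)
        by = table.groupby(["condition", "gene"])["ct"].mean().unstack()
        dct = by["GAPDH"] - by["ACTB"]
        assert dct["Osteo+"] == pytest.approx(dct["Xpan"])

    def test_non_positive_fold_rejected(self):
        with pytest.raises(SimulationError):
            simulate_ct_table({"ALPL": 0.0})


class TestFeatureTable:
    def test_row_identities_hold_exactly(self):
        tab = simulate_feature_table(n_images=5, seed=1)
        np.testing.assert_allclose(
            tab.tau_avg,
            tab.alpha1_frac * tab.tau1 + (1 - tab.alpha1_frac) * tab.tau2,
        )
        np.testing.assert_allclose(
            tab.orr, tab.fad_intensity / tab.nadph_intensity
        )

    def test_group_means_near_operating_points(self):
        tab = simulate_feature_table(n_images=200, seed=2)
        sub = tab[(tab.group == "Osteo+") & (tab.day == 14)]
        point = fm.OSTEO_TIMECOURSE["Osteo+"][14]
        for col in ("tau_avg", "tau1", "orr"):
            mean, sd = point[col]
            assert sub[col].mean() == pytest.approx(
                mean, abs=4 * sd / np.sqrt(len(sub))
            )

    def test_same_seed_identical(self):
        a = simulate_feature_table(n_images=4, seed=3)
        b = simulate_feature_table(n_images=4, seed=3)
        pd.testing.assert_frame_equal(a, b)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    tau1=st.floats(1.5, 5.0),
    tau2=st.floats(0.15, 0.9),
    a1f=st.floats(0.0, 1.0),
    photons=st.floats(1e3, 1e6),
)
def test_expected_counts_conserve_photons_and_stay_positive(
    tau1, tau2, a1f, photons
):
    """Property: bin expectations are positive and sum to the photon budget."""
    truth = DecayGroundTruth(
        tau1=tau1, tau2=tau2, alpha1_frac=a1f, total_photons=photons
    )
    lam = expected_decay_counts(truth, AcquisitionConfig())
    assert np.all(lam > 0)
    assert lam.sum() == pytest.approx(photons, rel=1e-9)
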