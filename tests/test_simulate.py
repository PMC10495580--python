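"""Synthetic cohort generator: lineshapes, artifacts, labels, determinism."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from specqc import (
    ArtifactProfile,
    MetabolitePeak,
    QCThresholds,
    SimulationConfig,
    assign_truth_label,
    canonical_axis,
    default_peaks,
    generate_cohort,
    inject_artifacts,
    preprocess_dataset,
    severity_score,
    simulate_clean_spectrum,
)
from specqc.simulate import _profile_from_severities, lorentzian


AXIS = canonical_axis()


class TestCleanSpectrum:
    def test_peak_height_at_center(self):
        s = simulate_clean_spectrum([MetabolitePeak("NAA", 2.01, 1.0, 0.035)], AXIS)
        i = np.argmin(np.abs(AXIS.ppm_values - 2.01))
        # grid offset can shave a little off a narrow Lorentzian's sampled peak
        assert s.intensities[i] == pytest.approx(1.0, abs=0.02)

    def test_half_maximum_at_half_width(self):
        peak = MetabolitePeak("X", 2.5, 2.0, 0.2)
        s = simulate_clean_spectrum([peak], AXIS)
        for side in (-1, 1):
            i = np.argmin(np.abs(AXIS.ppm_values - (2.5 + side * 0.1)))
            assert s.intensities[i] == pytest.approx(1.0, abs=0.02)

    def test_superposition(self):
        p1 = MetabolitePeak("a", 2.0, 1.0, 0.05)
        p2 = MetabolitePeak("b", 3.2, 0.7, 0.04)
        both = simulate_clean_spectrum([p1, p2], AXIS).intensities
        summed = (simulate_clean_spectrum([p1], AXIS).intensities
                  + simulate_clean_spectrum([p2], AXIS).intensities)
        assert np.allclose(both, summed, atol=1e-12)

    def test_linearity_in_amplitude(self):
        p = MetabolitePeak("a", 2.0, 1.0, 0.05)
        p3 = MetabolitePeak("a", 2.0, 3.0, 0.05)
        assert np.allclose(
            simulate_clean_spectrum([p3], AXIS).intensities,
            3 * simulate_clean_spectrum([p], AXIS).intensities,
        )

    def test_empty_peak_list_gives_flat_spectrum(self):
        assert not simulate_clean_spectrum([], AXIS).intensities.any()


class TestInjectArtifacts:
    def setup_method(self):
        self.clean = simulate_clean_spectrum(default_peaks(), AXIS)

    def test_identity_profile_is_identity(self):
        out = inject_artifacts(self.clean, ArtifactProfile(), np.random.default_rng(0))
        assert np.array_equal(out.intensities, self.clean.intensities)

    def test_frequency_shift_of_one_grid_step_rolls_by_one(self):
        profile = ArtifactProfile(freq_shift=AXIS.step)
        out = inject_artifacts(self.clean, profile, np.random.default_rng(0))
        assert np.array_equal(out.intensities, np.roll(self.clean.intensities, 1))

    def test_noise_standard_deviation_matches_monte_carlo(self):
        sigma = 0.37
        profile = ArtifactProfile(noise_sigma=sigma)
        rng = np.random.default_rng(123)
        reps = np.array(
            [inject_artifacts(self.clean, profile, rng).intensities for _ in range(10_000)]
        )
        per_point_std = (reps - self.clean.intensities).std(axis=0, ddof=1)
        assert np.all(np.abs(per_point_std - sigma) / sigma < 0.05)

    def test_broadening_widens_the_reference_peak(self):
        profile = ArtifactProfile(broadening_factor=2.5)
        out = inject_artifacts(self.clean, profile, np.random.default_rng(0)).intensities
        naa = np.argmin(np.abs(AXIS.ppm_values - 2.01))
        assert out[naa] < self.clean.intensities[naa]  # area conserved, peak lowered
        half = out[naa] / 2
        width_pts = np.sum(out[naa - 60: naa + 60] > half)
        base_half = self.clean.intensities[naa] / 2
        base_width = np.sum(self.clean.intensities[naa - 60: naa + 60] > base_half)
        assert width_pts > base_width

    def test_lipid_and_water_enter_at_window_edges(self):
        lip = inject_artifacts(self.clean, ArtifactProfile(lipid_amplitude=2.0),
                               np.random.default_rng(0)).intensities - self.clean.intensities
        assert lip[0] > lip[-1] and lip[0] > 0.5  # strongest at the 1.4 ppm edge
        wat = inject_artifacts(self.clean, ArtifactProfile(water_tail_amplitude=2.0),
                               np.random.default_rng(0)).intensities - self.clean.intensities
        assert wat[-1] > wat[0] and wat[-1] > 0.5  # strongest at the 4.1 ppm edge
        assert np.all(np.diff(wat) > 0)  # monotone tail toward the water side


class TestLabels:
    def setup_method(self):
        self.clean = simulate_clean_spectrum(default_peaks(), AXIS)
        self.thr = QCThresholds()

    def test_benign_profile_is_unanimously_good(self):
        profile = ArtifactProfile(noise_sigma=0.01, broadening_factor=1.0,
                                  lipid_amplitude=0.1, water_tail_amplitude=0.1)
        truth, label = assign_truth_label(profile, self.clean, self.thr,
                                          np.random.default_rng(0), rater_noise=0.0)
        assert (truth, label.rater_a, label.rater_b, label.consensus) == ("good",) * 4

    def test_single_exceeded_criterion_turns_consensus_bad(self):
        profile = ArtifactProfile(noise_sigma=0.01, lipid_amplitude=3.0)
        truth, label = assign_truth_label(profile, self.clean, self.thr,
                                          np.random.default_rng(0), rater_noise=0.0)
        assert truth == "bad" and label.consensus == "bad"

    def test_rater_disagreement_at_threshold_matches_flip_model(self):
        # at exactly-threshold severity with rater_noise=0.5 each rater is a
        # fair coin, so disagreement should be 2 * 0.5 * 0.5 = 0.5
        profile = _profile_from_severities(np.zeros(4), self.thr, np.random.default_rng(0))
        rng = np.random.default_rng(7)
        disagree = 0
        n = 10_000
        for _ in range(n):
            _, label = assign_truth_label(profile, self.clean, self.thr, rng, rater_noise=0.5)
            disagree += label.rater_a != label.rater_b
        assert abs(disagree / n - 0.5) < 0.03

    def test_severity_score_recovers_generated_margin_sign(self):
        rng = np.random.default_rng(3)
        for margin in (-0.8, -0.3, 0.3, 0.8):
            c = np.array([-0.9, -0.9, margin, -0.9])
            profile = _profile_from_severities(c, self.thr, rng)
            s = severity_score(profile, self.clean, self.thr)
            assert (s > 0) == (margin > 0)


class TestGenerateCohort:
    def test_identical_seed_gives_bit_identical_cohort(self):
        cfg = SimulationConfig(n_subjects=3, voxels_per_subject=15, seed=7)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        assert np.array_equal(a.spectra, b.spectra)
        assert a.manifest.equals(b.manifest)

    def test_realized_bad_fraction_tracks_target(self):
        cfg = SimulationConfig(n_subjects=8, voxels_per_subject=250, fraction_bad=0.46, seed=4)
        ds = generate_cohort(cfg)
        bad = 1 - ds.labels.mean()
        assert abs(bad - 0.46) < 0.03

    def test_zero_bad_fraction_yields_all_good(self):
        ds = generate_cohort(SimulationConfig(n_subjects=2, voxels_per_subject=40,
                                              fraction_bad=0.0, rater_noise=0.0, seed=1))
        assert (ds.manifest["consensus"] == "good").all()

    def test_full_separation_is_threshold_separable_on_severity(self, sep_cohort):
        m = sep_cohort.manifest
        good = m.loc[m.consensus == "good", "severity"]
        bad = m.loc[m.consensus == "bad", "severity"]
        # exhaustive scan: any threshold between the class extremes separates
        assert good.max() < 0 < bad.min()

    def test_zero_separation_severity_independent_of_label(self):
        ds = generate_cohort(SimulationConfig(n_subjects=4, voxels_per_subject=500,
                                              severity_separation=0.0, seed=5))
        m = ds.manifest
        res = mannwhitneyu(m.loc[m.consensus == "good", "severity"],
                           m.loc[m.consensus == "bad", "severity"])
        assert res.pvalue > 0.01
        assert abs((m.consensus == "bad").mean() - 0.46) < 0.03

    def test_generated_spectra_survive_preprocessing(self, sep_cohort):
        pp = preprocess_dataset(sep_cohort)
        assert np.allclose(pp.spectra.std(axis=1), 1.0, atol=1e-9)

    def test_tumor_mode_flags_lesions_and_suppresses_naa(self):
        ds = generate_cohort(SimulationConfig(n_subjects=4, voxels_per_subject=60,
                                              tumor_mode=True, lesion_fraction=0.5,
                                              fraction_bad=0.0, rater_noise=0.0, seed=8))
        assert set(ds.manifest["cohort_tag"]) == {"tumor"}
        mask = ds.lesion_mask
        assert 0 < mask.sum() < len(ds)
        naa = np.argmin(np.abs(ds.axis.ppm_values - 2.01))
        cho = np.argmin(np.abs(ds.axis.ppm_values - 3.22))
        lesion_ratio = (ds.spectra[mask, cho] / ds.spectra[mask, naa]).mean()
        normal_ratio = (ds.spectra[~mask, cho] / ds.spectra[~mask, naa]).mean()
        assert lesion_ratio > 2 * normal_ratio

    def test_restricted_criteria_suppress_other_artifacts(self):
        ds = generate_cohort(SimulationConfig(n_subjects=2, voxels_per_subject=30,
                                              criteria=("snr", "linewidth"), seed=3))
        # no lipid -> intensity near 1.4 ppm stays far below the lipid scale
        edge = ds.spectra[:, :10].mean()
        assert edge < 0.5

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(fraction_bad=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(n_subjects=0)
        with pytest.raises(ValueError):
            SimulationConfig(criteria=("snr", "ghost"))
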