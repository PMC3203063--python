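"""Model neurons: Gabor construction, nonlinearities, calibration, spiking."""

import numpy as np
import pytest

from quadrf import (
    GaborSpec,
    ModelCell,
    calibrate_scale,
    divisive_model_cell,
    divisive_rate,
    energy_model_cell,
    energy_rate,
    generate_naturalistic_patches,
    make_gabor,
    quadratic_logistic_cell,
    sample_spikes,
    spike_probability,
)
from quadrf.containers import StimulusEnsemble


class TestMakeGabor:
    def test_quadrature_pair_nearly_orthogonal(self):
        base = dict(center=(3.5, 3.5), orientation=0.7, frequency=0.3,
                    sigma=(2.0, 2.0))
        g0 = make_gabor(GaborSpec(phase=0.0, **base), 8, 8)
        g1 = make_gabor(GaborSpec(phase=np.pi / 2, **base), 8, 8)
        assert abs(g0 @ g1) < 0.1

    def test_unit_norm(self):
        g = make_gabor(GaborSpec(center=(2, 2), frequency=0.2), 6, 6)
        assert abs(np.linalg.norm(g) - 1.0) < 1e-12

    def test_annulus_mask_zeroes_center(self):
        spec = GaborSpec(center=(4, 4), frequency=0.3, sigma=(4, 4),
                         mask=("annulus", 2.0, 4.5))
        g = make_gabor(spec, 9, 9).reshape(9, 9)
        y, x = np.mgrid[0:9, 0:9]
        r = np.sqrt((x - 4.0) ** 2 + (y - 4.0) ** 2)
        assert np.all(g[r <= 2.0] == 0.0)

    def test_degenerate_spec_rejected(self):
        spec = GaborSpec(center=(100, 100), sigma=(0.5, 0.5))  # off-grid
        with pytest.raises(ValueError, match="zero energy"):
            make_gabor(spec, 8, 8)


class TestEnergyRate:
    def setup_method(self):
        self.cell = energy_model_cell(4, 4)
        self.cell.scale = 0.2
        self.e1, self.e2 = self.cell.excitatory_features

    def test_orthogonal_stimulus_gives_zero(self):
        s = np.ones(16) - self.e1 * (np.ones(16) @ self.e1) \
            - self.e2 * (np.ones(16) @ self.e2)
        assert energy_rate(self.cell, s) == pytest.approx(0.0, abs=1e-20)

    def test_phase_invariance(self):
        p1 = energy_rate(self.cell, self.e1)
        p2 = energy_rate(self.cell, (self.e1 + self.e2) / np.sqrt(2))
        assert p1 == pytest.approx(p2, rel=1e-10)

    def test_scaling_along_feature(self):
        for c in [0.5, 1.0, 3.0]:
            expected = min(1.0, self.cell.scale * c**2)
            assert energy_rate(self.cell, c * self.e1) == pytest.approx(expected)

    def test_rotation_in_excitatory_plane_is_invariant(self, rng):
        s = rng.standard_normal(16)
        basis = np.vstack([self.e1, self.e2])
        coeff = basis @ s
        residual = s - basis.T @ coeff
        for angle in [0.3, 1.1, 2.9]:
            rot = np.array([[np.cos(angle), -np.sin(angle)],
                            [np.sin(angle), np.cos(angle)]])
            s_rot = residual + basis.T @ (rot @ coeff)
            assert energy_rate(self.cell, s_rot) == pytest.approx(
                energy_rate(self.cell, s), rel=1e-10)


class TestDivisiveRate:
    def setup_method(self):
        self.cell = divisive_model_cell(8, 8)
        self.cell.scale = 0.3

    def test_six_features_have_rank_six(self):
        assert np.linalg.matrix_rank(self.cell.features) == 6

    def test_orthogonal_to_all_features_gives_zero(self):
        feats = self.cell.features
        s = np.random.default_rng(1).standard_normal(64)
        q = np.linalg.qr(feats.T, mode="reduced")[0]
        s -= q @ (q.T @ s)
        assert divisive_rate(self.cell, s) == pytest.approx(0.0, abs=1e-20)

    def test_monotone_decreasing_in_inhibition(self):
        # perturb along a direction that keeps the excitatory drive and the
        # other three inhibitory projections fixed, growing only |i1 . s|
        e1 = self.cell.excitatory_features[0]
        feats = self.cell.features
        q = np.linalg.qr(feats[[0, 1, 3, 4, 5]].T, mode="reduced")[0]
        i1 = self.cell.inhibitory_features[0]
        u = i1 - q @ (q.T @ i1)
        u /= np.linalg.norm(u)
        if i1 @ u < 0:
            u = -u
        probs = [divisive_rate(self.cell, e1 + c * u)
                 for c in [0.5, 1.0, 2.0, 4.0, 8.0]]
        assert all(a > b for a, b in zip(probs, probs[1:]))

    def test_zero_inhibition_reduces_to_energy(self):
        e_cell = ModelCell(self.cell.excitatory_features,
                           np.zeros((0, 64)), "energy", scale=self.cell.scale)
        e1 = self.cell.excitatory_features[0]
        q = np.linalg.qr(self.cell.inhibitory_features.T, mode="reduced")[0]
        s = e1 - q @ (q.T @ e1)
        assert divisive_rate(self.cell, s) == pytest.approx(
            energy_rate(e_cell, s), rel=1e-10)


class TestCalibrateScale:
    def test_target_operating_point_on_naturalistic_patches(self):
        ens = generate_naturalistic_patches(30000, 8, 8, 2.0, "lognormal", seed=31)
        cell = calibrate_scale(energy_model_cell(8, 8), ens, 0.15)
        mean_p = spike_probability(cell, ens).mean()
        assert 0.1485 <= mean_p <= 0.1515

    def test_half_rate_target_on_quadratic_cell(self, small_quadratic_dataset):
        ens, _, cell = small_quadratic_dataset
        recal = calibrate_scale(cell, ens, 0.5)
        assert spike_probability(recal, ens).mean() == pytest.approx(0.5, rel=0.01)

    def test_all_zero_stimulus_unreachable(self):
        ens = StimulusEnsemble(np.zeros((100, 16)), ("image", 4, 4))
        with pytest.raises(ValueError, match="unreachable"):
            calibrate_scale(energy_model_cell(4, 4), ens, 0.15)

    def test_divisive_cell_calibrates_too(self):
        ens = generate_naturalistic_patches(20000, 8, 8, 2.0, "lognormal", seed=32)
        cell = calibrate_scale(divisive_model_cell(8, 8), ens, 0.15)
        assert spike_probability(cell, ens).mean() == pytest.approx(0.15, rel=0.01)


class TestSampleSpikes:
    def test_zero_probability_bins_never_spike(self):
        cell = energy_model_cell(4, 4)
        cell.scale = 0.0
        ens = StimulusEnsemble(np.random.default_rng(0).standard_normal((500, 16)),
                               ("image", 4, 4))
        resp = sample_spikes(cell, ens, seed=1)
        assert resp.counts.sum() == 0

    def test_binary_mean_matches_calibrated_probability(self, small_quadratic_dataset):
        ens, _, cell = small_quadratic_dataset
        big = StimulusEnsemble(
            np.random.default_rng(5).standard_normal((100_000, ens.n_dims)),
            ens.geometry)
        cal = calibrate_scale(cell, big, 0.15)
        resp = sample_spikes(cal, big, seed=6)
        p = 0.15
        se = np.sqrt(p * (1 - p) / big.n_samples)
        assert abs(resp.binary.mean() - p) < 3 * se

    def test_fixed_seed_identical_trains(self, small_quadratic_dataset):
        ens, _, cell = small_quadratic_dataset
        a = sample_spikes(cell, ens, seed=9)
        b = sample_spikes(cell, ens, seed=9)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_multispike_bins_binarize_to_one(self, small_quadratic_dataset):
        ens, resp, _ = small_quadratic_dataset
        assert resp.binary.max() == 1.0
        assert np.all(resp.binary == np.minimum(resp.counts, 1))


def test_quadratic_logistic_truth_features_are_j_eigenvectors():
    j = np.diag([2.0, -1.0, 0.0, 0.0])
    cell = quadratic_logistic_cell(1.0, np.zeros(4), j)
    np.testing.assert_allclose(np.abs(cell.features[0]), [1, 0, 0, 0], atol=1e-12)
    np.testing.assert_allclose(np.abs(cell.features[1]), [0, 1, 0, 0], atol=1e-12)
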