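"""Information per spike, quadratic expansion, and MID optimisation."""

import numpy as np
import pytest
from scipy.special import expit

from quadrf import (
    SpikeResponse,
    diagonalize_quadratic,
    eigenvalue_significance,
    fit_minimal_model,
    fit_nmid,
    generate_gaussian,
    info_per_spike,
    info_permutation_null,
    model_projection,
    optimize_mid,
    quad_expand,
    subspace_projection,
)
from quadrf.containers import QuadraticModel, upper_triangle_indices
from quadrf.info_mid import soft_info_and_sample_grad


class TestQuadExpand:
    def test_two_dim_layout(self):
        s = np.array([[3.0, 5.0]])
        exp = quad_expand(s)
        np.testing.assert_allclose(exp.data[0], [3, 5, 9, 30, 25])
        assert exp.data.shape[1] == 2 + 3

    def test_reassembly_identity(self, rng):
        d = 6
        s = rng.standard_normal((40, d))
        h = rng.standard_normal(d)
        j = rng.standard_normal((d, d))
        j = (j + j.T) / 2
        iu, ju = upper_triangle_indices(d)
        v = np.concatenate([h, j[iu, ju]])
        direct = s @ h + np.einsum("ni,ni->n", s @ j, s)
        assert np.abs(quad_expand(s).data @ v - direct).max() < 1e-12

    def test_zero_stimulus_maps_to_zero(self):
        assert np.all(quad_expand(np.zeros((3, 4))).data == 0.0)

    def test_dimension_formula(self):
        for d in [1, 2, 5, 9]:
            exp = quad_expand(np.zeros((2, d)))
            assert exp.data.shape[1] == d + d * (d + 1) // 2
            assert len(exp.index_map) == exp.data.shape[1]


class TestInfoPerSpike:
    def test_half_mass_indicator_is_one_bit(self, rng):
        x = rng.standard_normal(100_000)
        r = (x > np.median(x)).astype(float)
        assert info_per_spike(x, r) == pytest.approx(1.0, abs=0.05)

    def test_hand_computed_three_bin_example(self):
        # prior uniform over 3 bins; spikes only in the top bin
        x = np.repeat([0.0, 1.0, 2.0], 100)
        r = np.zeros(300)
        r[200:] = 1.0
        # P(b|spike) = (0,0,1), P(b) = 1/3 each: KL = log2(3)
        assert info_per_spike(x, r, n_bins=3) == pytest.approx(np.log2(3.0),
                                                               abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x = rng.standard_normal(5000)
        r = (rng.random(5000) < expit(x)).astype(float)
        base = info_per_spike(x, r)
        assert info_per_spike(np.exp(x), r) == pytest.approx(base, abs=1e-12)
        assert info_per_spike(x**3, r) == pytest.approx(base, abs=1e-12)

    def test_independent_response_stays_below_permutation_bias(self, rng):
        x = rng.standard_normal(20_000)
        r = (rng.random(20_000) < 0.1).astype(float)
        draws = info_permutation_null(x, r, n_perm=130, seed=1)
        threshold = draws[:100].max()
        assert np.mean(draws[100:] <= threshold) >= 0.8
        assert draws.max() < 0.05

    def test_zero_spikes_rejected(self, rng):
        with pytest.raises(ValueError, match="spike"):
            info_per_spike(rng.standard_normal(100), np.zeros(100))

    def test_more_than_two_projections_rejected(self, rng):
        with pytest.raises(ValueError):
            info_per_spike(rng.standard_normal((100, 3)), np.ones(100))

    def test_nonnegative_and_two_dim_supported(self, rng):
        x = rng.standard_normal((5000, 2))
        r = (rng.random(5000) < 0.2).astype(float)
        assert info_per_spike(x, r) >= 0.0


class TestSoftSurrogateGradient:
    def test_matches_finite_differences(self, rng):
        x = rng.standard_normal(400)
        r = (rng.random(400) < 0.3).astype(float)
        centers = np.quantile(x, (np.arange(16) + 0.5) / 16)
        _, grad = soft_info_and_sample_grad(x, r, 16, centers)
        idx = rng.choice(400, 25, replace=False)
        for i in idx:
            e = np.zeros_like(x)
            e[i] = 1e-6
            up, _ = soft_info_and_sample_grad(x + e, r, 16, centers)
            dn, _ = soft_info_and_sample_grad(x - e, r, 16, centers)
            assert abs((up - dn) / 2e-6 - grad[i]) < 1e-6


def _single_feature_neuron(n=50_000, d=10, seed=70):
    rng = np.random.default_rng(seed)
    s = rng.standard_normal((n, d))
    w = np.zeros(d)
    w[0] = 1.0
    p = expit(-(1.5 - 2.0 * (s @ w)))
    r = SpikeResponse((rng.random(n) < p).astype(int))
    return s, r, w


class TestOptimizeMid:
    def test_recovers_single_feature(self):
        s, r, w = _single_feature_neuron()
        res = optimize_mid(s, r, n_dims=1, seed=3)
        assert subspace_projection(res.directions, w[None]) >= 0.95

    def test_true_direction_beats_random_directions(self):
        s, r, w = _single_feature_neuron(n=20_000)
        info_true = info_per_spike(s @ w, r.binary)
        rng = np.random.default_rng(4)
        for _ in range(20):
            v = rng.standard_normal(10)
            v /= np.linalg.norm(v)
            assert info_true >= info_per_spike(s @ v, r.binary)

    def test_fixed_seed_deterministic(self):
        s, r, _ = _single_feature_neuron(n=5000)
        a = optimize_mid(s, r, n_dims=1, seed=5, annealing=(0.02, 0.9, 15))
        b = optimize_mid(s, r, n_dims=1, seed=5, annealing=(0.02, 0.9, 15))
        np.testing.assert_array_equal(a.directions, b.directions)
        assert a.train_traces == b.train_traces

    def test_three_dims_unsupported(self):
        s, r, _ = _single_feature_neuron(n=1000)
        with pytest.raises(ValueError, match="at most 2"):
            optimize_mid(s, r, n_dims=3)

    def test_data_processing_inequality_on_average(self):
        # a sub-projection never carries more information than the pair
        rng = np.random.default_rng(6)
        diffs = []
        for _ in range(20):
            s = rng.standard_normal((4000, 4))
            p = expit(-(1.0 - 1.2 * s[:, 0] + 0.8 * s[:, 1]))
            r = (rng.random(4000) < p).astype(float)
            pair = info_per_spike(s[:, :2], r, n_bins=8)
            sub = info_per_spike(s[:, 0], r, n_bins=8)
            diffs.append(pair - sub)
        assert np.mean(diffs) > 0
        assert np.min(diffs) > -0.05  # within estimator noise


class TestFitNmid:
    def test_training_info_never_drops_below_init(self, small_quadratic_dataset):
        ens, resp, _ = small_quadratic_dataset
        mne = fit_minimal_model(ens, resp, folds=4, max_iter=60).model
        model = fit_nmid(ens, resp, mne, seed=7, annealing=(0.02, 0.9, 15))
        for trace in model.fit_traces["train"]:
            assert max(trace) >= trace[0] - 1e-12

    def test_mne_solution_beats_random_equal_norm_vectors(self,
                                                          small_quadratic_dataset):
        ens, resp, _ = small_quadratic_dataset
        mne = fit_minimal_model(ens, resp, folds=4, max_iter=60).model
        std = ens.standardized()
        proj = model_projection(mne, std.data)
        info_mne = info_per_spike(proj, resp.binary)
        d = ens.n_dims
        iu, ju = upper_triangle_indices(d)
        norm = np.linalg.norm(np.concatenate([mne.h, mne.j[iu, ju]]))
        rng = np.random.default_rng(8)
        for _ in range(50):
            v = rng.standard_normal(d + iu.size)
            v *= norm / np.linalg.norm(v)
            h, jt = v[:d], v[d:]
            jm = np.zeros((d, d))
            jm[iu, ju] = jt
            jm = (jm + np.triu(jm, 1).T)
            rand_model = QuadraticModel.from_full(0.0, h, jm)
            info_rand = info_per_spike(model_projection(rand_model, std.data),
                                       resp.binary)
            assert info_mne >= info_rand

    def test_purely_linear_cell_leaves_kernel_insignificant(self):
        rng = np.random.default_rng(9)
        d, n = 8, 30_000
        s = rng.standard_normal((n, d))
        w = np.zeros(d)
        w[0] = 1.0
        p = expit(-(2.0 - 1.5 * (s @ w)))
        from quadrf.containers import StimulusEnsemble

        ens = StimulusEnsemble(s, ("temporal", d, float("nan")))
        resp = SpikeResponse((rng.random(n) < p).astype(int))
        mne = fit_minimal_model(ens, resp, folds=4, max_iter=100).model
        model = fit_nmid(ens, resp, mne, seed=10, annealing=(0.02, 0.9, 15))
        fs, _ = eigenvalue_significance(model, seed=11)
        assert fs.significant.sum() <= 1  # kernel is noise
        # the linear kernel dominates every curvature direction
        assert np.linalg.norm(model.h) > 3 * np.abs(fs.eigenvalues).max()
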