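"""tICA, density clustering, boost reweighting and frame selection."""

import numpy as np
import pytest

from phquench.constants import K_B_KCAL
from phquench.landscape import (
    ClusterSet,
    FeatureMatrix,
    cluster_density,
    fit_tica,
    representative_frame,
    reweight_pmf,
    stratified_sample,
)
from phquench.synthgen import simulate_biased_samples


def ar1_series(n, tau, seed, sd=1.0):
    phi = np.exp(-1.0 / tau)
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = rng.normal(0, sd)
    eps = rng.normal(0, sd * np.sqrt(1 - phi**2), size=n)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t]
    return x


class TestTica:
    def test_slow_mode_identification(self):
        """First tIC aligns with the slow AR(1) feature."""
        n = 20_000
        slow = ar1_series(n, tau=100, seed=0)
        fast = ar1_series(n, tau=2, seed=1)
        model = fit_tica(np.column_stack([slow, fast]), lag=50, n_dims=2)
        v = model.components_[:, 0]
        cos = abs(v[0]) / np.linalg.norm(v)
        assert cos > 0.99
        assert model.eigenvalues_[0] > model.eigenvalues_[1]

    def test_matches_dense_generalized_eigensolver(self):
        """Eigenvalues agree with an independent numpy route to 1e-8."""
        rng = np.random.default_rng(5)
        x = rng.normal(size=(3000, 10)) @ rng.normal(size=(10, 10))
        model = fit_tica(x, lag=5, n_dims=10)
        # independent oracle: plain eigendecomposition of C0^-1 C(tau)
        d = x.shape[1]
        reg = model.ridge * np.trace(model.c0_) / d
        vals = np.linalg.eigvals(np.linalg.solve(model.c0_ + reg * np.eye(d), model.ctau_))
        assert np.allclose(np.sort(vals.real), np.sort(model.eigenvalues_), atol=1e-8)

    def test_periodic_series_gives_unit_eigenvalue(self):
        """When x(t+lag) = x(t) exactly, the top eigenvalue reaches 1."""
        base = np.random.default_rng(2).normal(size=(50, 2))
        x = np.tile(base, (40, 1))
        model = fit_tica(x, lag=50, n_dims=2, ridge=1e-12)
        assert model.eigenvalues_[0] == pytest.approx(1.0, abs=1e-6)

    def test_training_projection_unit_variance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(5000, 4))
        model = fit_tica(x, lag=3, n_dims=2)
        proj = model.transform(x)
        assert np.allclose(proj.var(axis=0, ddof=0), 1.0, atol=0.01)

    def test_mean_input_projects_to_zero(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(1000, 3)) + 5.0
        model = fit_tica(x, lag=2)
        proj = model.transform(np.tile(model.means_, (4, 1)))
        assert np.allclose(proj, 0.0, atol=1e-12)

    def test_eigenvalues_invariant_under_linear_reparameterization(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(4000, 5))
        x[:, 0] = ar1_series(4000, 30, seed=7)
        a = rng.normal(size=(5, 5)) + 3 * np.eye(5)  # well-conditioned invertible map
        m1 = fit_tica(x, lag=10, n_dims=5, ridge=1e-12)
        m2 = fit_tica(x @ a, lag=10, n_dims=5, ridge=1e-12)
        assert np.allclose(m1.eigenvalues_, m2.eigenvalues_, atol=1e-6)

    def test_feature_name_mismatch(self):
        fm = FeatureMatrix(np.random.default_rng(0).normal(size=(200, 2)), ["a", "b"])
        model = fit_tica(fm, lag=2)
        with pytest.raises(ValueError, match="feature names"):
            model.transform(FeatureMatrix(fm.values, ["a", "c"]))

    def test_too_few_frames(self):
        with pytest.raises(ValueError, match="frames"):
            fit_tica(np.zeros((5, 4)), lag=3)


class TestClustering:
    def test_two_separated_blobs(self):
        rng = np.random.default_rng(1)
        pts = np.vstack(
            [rng.normal([0, 0], 0.1, (500, 2)), rng.normal([10, 0], 0.1, (500, 2))]
        )
        cs = cluster_density(pts, min_cluster_size=50)
        assert len(cs.cluster_ids) == 2
        lab_left = cs.labels[:500]
        lab_right = cs.labels[500:]
        purity = max(np.mean(lab_left == c) for c in cs.cluster_ids) + max(
            np.mean(lab_right == c) for c in cs.cluster_ids
        )
        assert purity > 1.98  # >= 99% correct on each blob

    def test_uniform_noise_no_clusters(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-1, 1, size=(300, 2))
        with pytest.warns(UserWarning, match="noise"):
            cs = cluster_density(pts, min_cluster_size=200)
        assert cs.cluster_ids == []

    def test_composition_bookkeeping(self):
        rng = np.random.default_rng(3)
        pts = np.vstack(
            [rng.normal([0, 0], 0.1, (200, 2)), rng.normal([8, 0], 0.1, (100, 2))]
        )
        pms = np.array(["PPD"] * 180 + ["DPP"] * 20 + ["PDP"] * 100)
        cs = cluster_density(pts, min_cluster_size=50, pms=pms)
        # identify the cluster holding the mixed blob by its location
        mixed = int(cs.labels[0])
        comp = cs.composition(mixed)
        assert comp == {"PPD": pytest.approx(0.9, abs=0.02), "DPP": pytest.approx(0.1, abs=0.02)}

    def test_label_partition_reproducible(self):
        rng = np.random.default_rng(4)
        pts = np.vstack([rng.normal([0, 0], 0.2, (300, 2)), rng.normal([5, 5], 0.2, (300, 2))])
        a = cluster_density(pts, min_cluster_size=50).labels
        b = cluster_density(pts, min_cluster_size=50).labels
        assert np.array_equal(a, b)


class TestReweighting:
    def test_zero_boost_equals_plain_histogram(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=2000)
        kt = K_B_KCAL * 300.0
        pmf = reweight_pmf(pts, None, bins=20, n_min=5)
        counts, _ = np.histogram(pts, bins=pmf.edges[0])
        ref = -kt * np.log(counts / counts.sum())
        ref -= ref[counts >= 5].min()
        mask = counts >= 5
        assert np.allclose(pmf.free_energy[mask], ref[mask], atol=1e-12)

    def test_constant_boost_cancels(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=2000)
        p0 = reweight_pmf(pts, np.zeros(2000), bins=20, n_min=5)
        p5 = reweight_pmf(pts, np.full(2000, 5.0), bins=20, n_min=5)
        m = p0.reliable & p5.reliable
        assert np.allclose(p0.free_energy[m], p5.free_energy[m], atol=1e-10)

    def test_double_well_recovery(self):
        """Reweighted profile recovers the known double-well to < 0.5 kT."""
        kt = K_B_KCAL * 300.0
        grid = np.linspace(-2.0, 2.0, 801)
        f_true = 2.0 * (grid**2 - 1.0) ** 2  # wells at +-1, 2 kcal/mol barrier

        def boost(x):
            return 1.6 * np.exp(-((x**2 - 1.0) ** 2))  # well-filling

        sample = simulate_biased_samples((grid, f_true), boost, 150_000, seed=9, boost_sd=0.3)
        pmf = reweight_pmf(sample.cv_values, sample.boost, bins=40, n_min=200)
        centers = pmf.centers[0]
        mask = pmf.reliable & (pmf.counts > 0)
        truth = sample.truth_pmf(centers[mask])
        truth = truth - truth.min()
        est = pmf.free_energy[mask]
        est = est - est.min()
        assert np.nanmax(np.abs(est - truth)) < 0.5 * kt

    def test_underoccupied_bins_masked(self):
        pts = np.concatenate([np.zeros(100), [10.0]])
        pmf = reweight_pmf(pts, None, bins=10, n_min=10)
        assert np.isnan(pmf.free_energy[-1])
        assert pmf.free_energy[0] == 0.0

    def test_misaligned_boost_rejected(self):
        with pytest.raises(ValueError, match="align"):
            reweight_pmf(np.zeros(10), np.zeros(9))


class TestSampling:
    def _clusters(self, comp, n=200):
        labels = np.zeros(n, dtype=int)
        pms = np.concatenate(
            [np.full(int(round(frac * n)), name) for name, frac in comp.items()]
        )
        return ClusterSet(labels=labels[: pms.size], pms=pms)

    def test_exact_rounding_90_10(self):
        cs = self._clusters({"PPD": 0.9, "DPP": 0.1})
        picks = stratified_sample(cs, 30, seed=0)[0]
        drawn = cs.pms[picks]
        assert (drawn == "PPD").sum() == 27 and (drawn == "DPP").sum() == 3

    def test_exact_rounding_three_strata(self):
        cs = self._clusters({"A": 0.5, "B": 0.3, "C": 0.2})
        drawn = cs.pms[stratified_sample(cs, 30, seed=1)[0]]
        assert [(drawn == s).sum() for s in "ABC"] == [15, 9, 6]

    def test_single_stratum(self):
        cs = self._clusters({"PDP": 1.0})
        assert stratified_sample(cs, 30, seed=2)[0].size == 30

    def test_small_stratum_falls_back_with_replacement(self):
        labels = np.zeros(12, dtype=int)
        pms = np.array(["A"] * 2 + ["B"] * 10)
        cs = ClusterSet(labels=labels, pms=pms)
        with pytest.warns(UserWarning, match="replacement"):
            picks = stratified_sample(cs, 30, seed=3)
        assert picks[0].size == 30

    def test_reproducible(self):
        cs = self._clusters({"A": 0.6, "B": 0.4})
        a = stratified_sample(cs, 20, seed=9)[0]
        b = stratified_sample(cs, 20, seed=9)[0]
        assert np.array_equal(a, b)


class TestRepresentativeFrame:
    def test_central_point_of_symmetric_triple(self):
        pts = np.array([[-1.0, 0.0], [0.0, 0.0], [1.0, 0.0]])
        cs = ClusterSet(labels=np.zeros(3, dtype=int))
        assert representative_frame(cs, pts)[0] == 1

    def test_singleton_cluster(self):
        cs = ClusterSet(labels=np.array([0]))
        assert representative_frame(cs, np.array([[3.0, 4.0]]))[0] == 0

    def test_gaussian_blob_pick_is_near_center(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(2000, 2))
        cs = ClusterSet(labels=np.zeros(2000, dtype=int))
        pick = representative_frame(cs, pts)[0]
        d = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
        assert d[pick] <= np.percentile(d, 10)
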