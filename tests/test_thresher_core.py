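"""Loadings, outlier filtering, the vMF mixture EM, and the two-pass run."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from thresher.containers import ExpressionMatrix
from thresher.synthetic_data import generate_factor_dataset, sample_vmf
from thresher.thresher_core import (
    OUTLIER,
    LoadingMatrix,
    filter_outliers,
    fit_vmf_mixture,
    gene_loadings,
    run_thresher,
    select_clusters,
    validate_cluster_unidimensionality,
    vmf_log_density,
)


class TestGeneLoadings:
    def test_two_perfectly_correlated_genes(self):
        row = np.arange(6.0)
        m = ExpressionMatrix(pd.DataFrame([row, 2 * row + 1], index=["a", "b"]))
        load = gene_loadings(m, 1)
        assert np.allclose(load.weights.to_numpy(), 1.0, atol=1e-10)

    def test_weights_are_gene_pc_correlations(self, signal_only):
        m, _ = signal_only
        D = 5
        load = gene_loadings(m, D)
        X = m.to_array()
        Z = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=1, keepdims=True)
        # PC-j sample scores from the eigenvectors recovered off the weights
        lam = np.sum(load.weights.to_numpy() ** 2, axis=0)
        V = load.weights.to_numpy() / np.sqrt(lam)
        scores = Z.T @ V
        for j in range(D):
            r = [np.corrcoef(X[i], scores[:, j])[0, 1] for i in range(m.n_genes)]
            assert np.allclose(load.weights.to_numpy()[:, j], r, atol=1e-8)

    def test_independent_gene_has_small_magnitude(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(800)
        rows = [z + 0.1 * rng.standard_normal(800) for _ in range(6)]
        rows.append(rng.standard_normal(800))  # unrelated gene
        m = ExpressionMatrix(pd.DataFrame(rows))
        load = gene_loadings(m, 1)
        mags = load.magnitudes
        assert mags.iloc[:6].min() > 0.9
        assert mags.iloc[6] < 0.2

    def test_d_beyond_rank_errors(self, tiny_matrix):
        with pytest.raises(ValueError, match="rank"):
            gene_loadings(tiny_matrix, 10)

    def test_magnitude_bounded_by_one(self, bundle):
        m, _ = bundle
        load = gene_loadings(m, 5)
        assert load.magnitudes.max() <= 1.0 + 1e-8


class TestFilterOutliers:
    def test_strict_inequality_boundary(self):
        w = pd.DataFrame(
            {"PC1": [0.29, 0.30, 0.31]}, index=["g1", "g2", "g3"]
        )
        kept, out = filter_outliers(LoadingMatrix(w), cutoff=0.3)
        assert out == ["g1"]
        assert kept == ["g2", "g3"]

    def test_all_removed_advises_lower_cutoff(self):
        w = pd.DataFrame({"PC1": [0.1, 0.2]}, index=["a", "b"])
        with pytest.raises(ValueError, match="lower the cutoff"):
            filter_outliers(LoadingMatrix(w), cutoff=0.3)

    def test_bad_cutoff_rejected(self):
        w = pd.DataFrame({"PC1": [0.5]}, index=["a"])
        for bad in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                filter_outliers(LoadingMatrix(w), cutoff=bad)

    def test_noise_vs_factor_separation_on_bundle(self, bundle):
        m, t = bundle
        load = gene_loadings(m, t.n_factors)
        kept, out = filter_outliers(load, cutoff=0.3)
        assert set(out) == set(t.noise_genes())
        assert set(kept) == set(t.signal_genes())

    def test_factor_genes_retained_at_low_noise(self):
        m, t = generate_factor_dataset(
            n_samples=500, n_factors=5, genes_per_factor=8,
            n_noise_genes=10, noise_sd=0.3, seed=17,
        )
        kept, out = filter_outliers(gene_loadings(m, 5), cutoff=0.3)
        assert set(t.signal_genes()) <= set(kept)  # specificity
        assert set(out) <= set(t.noise_genes())


class TestVMFMixture:
    def test_uniform_density_on_sphere_p3(self):
        x = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        val = vmf_log_density(x, np.array([0.0, 1.0, 0.0]), 0.0)
        assert np.allclose(np.exp(val), 1.0 / (4 * np.pi))

    def test_density_integrates_to_one_p2(self):
        # circle case: integrate exp-density over angle
        mu = np.array([1.0, 0.0])
        theta = np.linspace(0, 2 * np.pi, 20_001)
        pts = np.column_stack([np.cos(theta), np.sin(theta)])
        dens = np.exp(vmf_log_density(pts, mu, 3.7))
        assert abs(np.trapezoid(dens, theta) - 1.0) < 1e-6

    def test_single_component_mean_is_resultant_direction(self):
        pts = np.array([[1.0, 0.0], [0.0, 1.0]])
        fit = fit_vmf_mixture(pts, K=1, n_restarts=2, seed=0)
        mu = fit.components[0].mean_direction
        assert np.allclose(mu, [1 / np.sqrt(2), 1 / np.sqrt(2)], atol=1e-8)

    def test_two_component_recovery_and_loglik_oracle(self):
        mu1 = np.array([1.0, 0.0, 0.0])
        mu2 = np.array([0.0, 1.0, 0.0])
        x = np.vstack(
            [sample_vmf(mu1, 50.0, 200, seed=1), sample_vmf(mu2, 50.0, 200, seed=2)]
        )
        fit = fit_vmf_mixture(x, K=2, seed=0)
        # recovered means within 5 degrees, kappa within 15% relative
        found = sorted(
            fit.components, key=lambda c: -abs(c.mean_direction[0])
        )
        for comp, mu in zip(found, [mu1, mu2]):
            angle = np.degrees(
                np.arccos(np.clip(abs(comp.mean_direction @ mu), -1, 1))
            )
            assert angle < 5.0
            assert abs(comp.concentration - 50.0) / 50.0 < 0.15
        # independent direct-summation oracle for the mixture log-likelihood
        log_terms = np.column_stack(
            [
                np.log(c.weight) + vmf_log_density(x, c.mean_direction, c.concentration)
                for c in fit.components
            ]
        )
        m = log_terms.max(axis=1, keepdims=True)
        oracle_ll = float((m[:, 0] + np.log(np.exp(log_terms - m).sum(1))).sum())
        assert np.isclose(fit.log_likelihood, oracle_ll, rtol=1e-8)
        # AIC bookkeeping is exact: 2(KD + K - 1) - 2 logL
        assert fit.aic == pytest.approx(2 * (2 * 3 + 1) - 2 * fit.log_likelihood)

    def test_em_trace_monotone_and_responsibilities_normalized(self):
        x = sample_vmf(np.array([0.0, 0.0, 1.0]), 10.0, 150, seed=3)
        fit = fit_vmf_mixture(x, K=3, seed=1)
        assert np.all(np.diff(fit.log_likelihood_trace) >= -1e-9)
        assert np.allclose(fit.responsibilities.sum(axis=1), 1.0, atol=1e-10)

    def test_determinism_given_seed(self):
        x = sample_vmf(np.array([1.0, 0.0, 0.0]), 5.0, 100, seed=4)
        a = fit_vmf_mixture(x, K=2, seed=9)
        b = fit_vmf_mixture(x, K=2, seed=9)
        assert a.log_likelihood == b.log_likelihood
        assert np.array_equal(a.responsibilities, b.responsibilities)

    def test_invalid_inputs(self):
        ok = np.array([[1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="K must satisfy"):
            fit_vmf_mixture(ok, K=3)
        with pytest.raises(ValueError, match="unit"):
            fit_vmf_mixture(2 * ok, K=1)


class TestSelectClusters:
    def test_d1_candidates_are_one_and_two(self):
        x = sample_vmf(np.array([1.0, 0.0]), 20.0, 40, seed=0)
        fit, K = select_clusters(x, D=1, seed=0, n_restarts=5)
        assert K in (1, 2)
        assert fit.n_components == K

    def test_sign_split_factor_doubles_cluster(self):
        # three factors, one split into +/- halves: the split genes point in
        # opposite directions, so K = 4 and the sign groups never co-cluster
        m, t = generate_factor_dataset(
            n_samples=500, n_factors=3, genes_per_factor=8,
            frac_negative_sign=(0.0, 0.0, 0.5), noise_sd=1.0, seed=7,
        )
        load = gene_loadings(m, 3)
        fit, K = select_clusters(load.directions(), 3, seed=7, kappa_max=500.0)
        assert K == 4
        labels = fit.hard_assignment()
        genes = list(m.genes)
        neg = {labels[i] for i, g in enumerate(genes) if t.sign_of_gene[g] == -1}
        pos = {
            labels[i]
            for i, g in enumerate(genes)
            if t.factor_of_gene[g] == 2 and t.sign_of_gene[g] == 1
        }
        assert neg.isdisjoint(pos)

    def test_too_few_points_error(self):
        x = np.array([[1.0, 0.0]])
        with pytest.raises(ValueError, match="at least"):
            select_clusters(x, D=2)


class TestRunThresher:
    def test_bundle_recovery_is_exact(self, bundle):
        m, t = bundle
        res = run_thresher(m, seed=3)
        assert set(res.outliers) == set(t.noise_genes())
        assert res.dimension == t.n_factors
        assert res.n_clusters == t.n_planted_clusters()
        assert res.dimension <= res.n_clusters <= 2 * res.dimension
        truth = t.cluster_labels()
        kept = [g for g in m.genes if res.assignment[g] != OUTLIER]
        ari = adjusted_rand_score(
            [truth[g] for g in kept], [res.assignment[g] for g in kept]
        )
        assert ari == 1.0
        assert all(v["valid"] for v in res.validation.values())

    def test_antipodal_sign_groups_never_co_cluster(self, bundle):
        m, t = bundle
        res = run_thresher(m, seed=3)
        split = [g for g in t.signal_genes() if t.factor_of_gene[g] == 4]
        neg = {res.assignment[g] for g in split if t.sign_of_gene[g] == -1}
        pos = {res.assignment[g] for g in split if t.sign_of_gene[g] == 1}
        assert neg.isdisjoint(pos)

    def test_single_factor_matrix(self):
        m, _ = generate_factor_dataset(
            n_samples=300, n_factors=1, genes_per_factor=10, noise_sd=1.0, seed=2
        )
        res = run_thresher(m, seed=2)
        assert res.dimension == 1
        assert res.n_clusters in (1, 2)
        non_outlier = [c for c in res.assignment if c != OUTLIER]
        assert len(set(non_outlier)) == 1  # no sign split planted

    def test_gene_order_permutation_invariance(self, bundle):
        m, _ = bundle
        res_a = run_thresher(m, seed=5)
        rng = np.random.default_rng(0)
        perm = rng.permutation(m.n_genes)
        m_perm = ExpressionMatrix(m.values.iloc[perm])
        res_b = run_thresher(m_perm, seed=5)
        genes = list(m.genes)
        a = [res_a.assignment[g] for g in genes]
        b = [res_b.assignment[g] for g in genes]
        assert (np.array(a) == OUTLIER).tolist() == (np.array(b) == OUTLIER).tolist()
        kept = [i for i, v in enumerate(a) if v != OUTLIER]
        assert adjusted_rand_score([a[i] for i in kept], [b[i] for i in kept]) == 1.0

    def test_constant_gene_becomes_outlier(self, bundle):
        m, _ = bundle
        vals = m.values.copy()
        vals.loc["CONST"] = 3.14
        with pytest.warns(UserWarning, match="constant gene"):
            res = run_thresher(ExpressionMatrix(vals), seed=1)
        assert "CONST" in res.outliers

    def test_every_gene_assigned_exactly_once(self, bundle):
        m, _ = bundle
        res = run_thresher(m, seed=8)
        assert set(res.assignment.index) == set(m.genes)
        assert res.assignment.notna().all()


class TestValidation:
    def test_perfect_cluster(self):
        row = np.arange(8.0)
        rng = np.random.default_rng(0)
        rows = [row + 1e-9 * rng.standard_normal(8) for _ in range(3)]
        m = ExpressionMatrix(pd.DataFrame(rows, index=["a", "b", "c"]))
        rep = validate_cluster_unidimensionality(m, ["a", "b", "c"])
        assert rep["dimension"] <= 1
        assert rep["first_pc_variance_fraction"] > 0.999
        assert rep["same_sign"] is True
        assert rep["valid"] is True

    def test_anticorrelated_pair_fails_same_sign(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal(100)
        m = ExpressionMatrix(
            pd.DataFrame([z, -z + 0.01 * rng.standard_normal(100)], index=["up", "dn"])
        )
        rep = validate_cluster_unidimensionality(m, ["up", "dn"])
        assert rep["same_sign"] is False
        assert rep["valid"] is False

    def test_singleton_cluster_is_trivially_valid(self, bundle):
        m, _ = bundle
        rep = validate_cluster_unidimensionality(m, [m.genes[0]])
        assert rep == {
            "n_members": 1,
            "dimension": 1,
            "first_pc_variance_fraction": 1.0,
            "same_sign": True,
            "valid": True,
        }

    def test_empty_cluster_errors(self, bundle):
        m, _ = bundle
        with pytest.raises(ValueError, match="no members"):
            validate_cluster_unidimensionality(m, [])
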