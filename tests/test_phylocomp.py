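import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from coevoscan import phylocomp, synthdata
from coevoscan.phylocomp import (
    GeneEvolSummary,
    brownian_cov,
    convergence_diagnostics,
    effective_sample_size,
    lrt,
    parse_coevol_trace,
    partial_correlation,
    permutation_null,
    pgls_fit,
    pic_correlation,
    posterior_summary,
    rank_focal,
    residual_r2,
)

from conftest import star_tree


class TestPGLS:
    def test_identity_covariance_equals_ols(self, rng):
        n = 25
        x = rng.standard_normal(n)
        y = 1.0 + 2.0 * x + rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x])
        fit = pgls_fit(y, X, np.eye(n))
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.coef, ols, rtol=1e-8)

    def test_constant_response_no_signal(self, yule30):
        cov = brownian_cov(yule30)
        n = yule30.n_leaves
        y = np.full(n, 3.0)
        x = np.arange(n, dtype=float)
        full = pgls_fit(y, np.column_stack([np.ones(n), x]), cov)
        null = pgls_fit(y, np.ones((n, 1)), cov)
        assert full.coef[1] == pytest.approx(0.0, abs=1e-10)
        stat, df, p = lrt(full, null)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_slope_recovery_under_brownian_noise(self, yule30):
        """y = 2x + Brownian noise on a 30-leaf tree: the mean GLS slope over
        200 replicates recovers the simulated slope."""
        cov = brownian_cov(yule30).values
        L = np.linalg.cholesky(cov)
        n = yule30.n_leaves
        rng = np.random.default_rng(7)
        slopes = []
        for _ in range(200):
            x = L @ rng.standard_normal(n)
            y = 2.0 * x + L @ rng.standard_normal(n)
            fit = pgls_fit(y, np.column_stack([np.ones(n), x]), cov)
            slopes.append(fit.coef[1])
        assert 1.9 <= np.mean(slopes) <= 2.1

    def test_singular_design_raises(self, yule30):
        cov = brownian_cov(yule30)
        n = yule30.n_leaves
        X = np.column_stack([np.ones(n), np.ones(n)])
        with pytest.raises(ValueError, match="singular design"):
            pgls_fit(np.arange(n, dtype=float), X, cov)

    def test_singular_cov_suggests_ridge(self):
        n = 4
        cov = np.zeros((n, n))
        with pytest.raises(ValueError, match="ridge"):
            pgls_fit(np.arange(n, dtype=float), np.ones((n, 1)), cov)


class TestLRT:
    def test_identical_models(self, yule30):
        cov = brownian_cov(yule30)
        y = np.arange(yule30.n_leaves, dtype=float)
        fit = pgls_fit(y, np.ones((len(y), 1)), cov)
        stat, df, p = lrt(fit, fit)
        assert stat == 0 and df == 0 and p == 1.0

    def test_chi2_tail_value(self):
        # chi-square survival at 10.04 with 1 df, checked against scipy's table
        a = GeneEvolSummary  # noqa: F841  (no-op to keep imports honest)
        assert stats.chi2.sf(10.04, 1) == pytest.approx(0.00153, rel=5e-3)

    def test_different_n_rejected(self, yule30):
        cov = brownian_cov(yule30)
        y = np.arange(yule30.n_leaves, dtype=float)
        full = pgls_fit(y, np.ones((len(y), 1)), cov)
        null = pgls_fit(y[:-1], np.ones((len(y) - 1, 1)), cov.iloc[:-1, :-1])
        with pytest.raises(ValueError):
            lrt(full, null)

    def test_null_pvalues_uniform(self):
        """Under no association the LRT p-values are approximately uniform."""
        tree = synthdata.simulate_tree(30, seed=21)
        cov = brownian_cov(tree).values
        L = np.linalg.cholesky(cov)
        n = tree.n_leaves
        rng = np.random.default_rng(3)
        pvals = []
        X0 = np.ones((n, 1))
        for _ in range(1000):
            x = L @ rng.standard_normal(n)
            y = L @ rng.standard_normal(n)
            full = pgls_fit(y, np.column_stack([X0, x]), cov)
            null = pgls_fit(y, X0, cov)
            pvals.append(lrt(full, null)[2])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestResidualR2:
    def test_zero_for_identical_fits(self, yule30):
        cov = brownian_cov(yule30)
        y = np.arange(yule30.n_leaves, dtype=float)
        fit = pgls_fit(y, np.ones((len(y), 1)), cov)
        assert residual_r2(fit, fit) == 0.0

    def test_one_for_noiseless_fit_on_star_tree(self):
        tree = star_tree(10)
        cov = brownian_cov(tree)
        x = np.arange(10, dtype=float)
        y = 3.0 + 0.5 * x
        full = pgls_fit(y, np.column_stack([np.ones(10), x]), cov)
        null = pgls_fit(y, np.ones((10, 1)), cov)
        assert residual_r2(full, null) == pytest.approx(1.0, abs=1e-6)

    def test_monotone_in_signal_to_noise(self):
        tree = synthdata.simulate_tree(25, seed=13)
        cov = brownian_cov(tree).values
        L = np.linalg.cholesky(cov)
        n = 25
        rng = np.random.default_rng(5)
        x = L @ rng.standard_normal(n)
        noise = L @ rng.standard_normal(n)
        r2s = []
        for beta in (0.2, 1.0, 5.0):
            y = beta * x + noise
            full = pgls_fit(y, np.column_stack([np.ones(n), x]), cov)
            null = pgls_fit(y, np.ones((n, 1)), cov)
            r2s.append(residual_r2(full, null))
        assert r2s[0] < r2s[1] < r2s[2]


class TestPIC:
    def test_exact_linearity(self, yule30):
        rng = np.random.default_rng(1)
        a = {s: rng.standard_normal() for s in yule30.leaf_labels}
        b = {s: 3.0 * v for s, v in a.items()}
        r, _ = pic_correlation(yule30, a, b)
        assert r == pytest.approx(1.0)

    def test_location_invariance(self, yule30):
        rng = np.random.default_rng(2)
        a = {s: rng.standard_normal() for s in yule30.leaf_labels}
        b = {s: rng.standard_normal() for s in yule30.leaf_labels}
        r1, _ = pic_correlation(yule30, a, b)
        r2, _ = pic_correlation(yule30, {s: v + 100 for s, v in a.items()}, b)
        assert r1 == pytest.approx(r2, rel=1e-10)

    def test_independent_traits_centred_at_zero(self):
        tree = synthdata.simulate_tree(30, seed=17)
        cov = brownian_cov(tree).values
        L = np.linalg.cholesky(cov)
        rng = np.random.default_rng(4)
        labels = tree.leaf_labels
        rs = []
        for _ in range(500):
            a = dict(zip(labels, L @ rng.standard_normal(30)))
            b = dict(zip(labels, L @ rng.standard_normal(30)))
            rs.append(pic_correlation(tree, a, b)[0])
        assert abs(np.mean(rs)) < 0.05


class TestPartialCorrelation:
    def test_identity(self):
        np.testing.assert_allclose(partial_correlation(np.eye(4)), np.eye(4))

    def test_equicorrelated_closed_form(self):
        C = np.full((3, 3), 0.5)
        np.fill_diagonal(C, 1.0)
        P = partial_correlation(C)
        off = P[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 1.0 / 3.0, rtol=1e-12)
        np.testing.assert_allclose(np.diag(P), 1.0)

    @staticmethod
    def bruteforce_partial(C):
        """Partial correlations as correlations of residuals after regressing
        out every remaining variable (population formulae on the covariance)."""
        k = C.shape[0]
        out = np.eye(k)
        for i in range(k):
            for j in range(i + 1, k):
                rest = [m for m in range(k) if m not in (i, j)]
                if not rest:
                    out[i, j] = out[j, i] = C[i, j] / np.sqrt(C[i, i] * C[j, j])
                    continue
                Crr = C[np.ix_(rest, rest)]
                ci = C[np.ix_([i], rest)].ravel()
                cj = C[np.ix_([j], rest)].ravel()
                sol = np.linalg.solve(Crr, np.column_stack([ci, cj]))
                vii = C[i, i] - ci @ sol[:, 0]
                vjj = C[j, j] - cj @ sol[:, 1]
                vij = C[i, j] - ci @ sol[:, 1]
                out[i, j] = out[j, i] = vij / np.sqrt(vii * vjj)
        return out

    def test_matches_residual_bruteforce_on_random_pd_matrices(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            k = int(rng.integers(3, 7))
            A = rng.standard_normal((k, k + 3))
            S = A @ A.T
            d = np.sqrt(np.diag(S))
            C = S / np.outer(d, d)
            np.testing.assert_allclose(
                partial_correlation(C), self.bruteforce_partial(C), atol=1e-8
            )

    def test_singular_matrix_suggests_shrinkage(self):
        C = np.ones((3, 3))
        with pytest.raises(ValueError, match="shrinkage"):
            partial_correlation(C)


class TestPermutationNull:
    @pytest.fixture
    def setup(self):
        tree = synthdata.simulate_tree(12, seed=31)
        cov = brownian_cov(tree)
        L = np.linalg.cholesky(cov.values)
        rng = np.random.default_rng(6)
        labels = tree.leaf_labels
        trait = dict(zip(labels, L @ rng.standard_normal(12)))
        focal = dict(zip(labels, L @ rng.standard_normal(12)))
        pool = {
            f"p{i}": dict(zip(labels, L @ rng.standard_normal(12))) for i in range(25)
        }
        return cov, trait, focal, pool

    def test_deterministic(self, setup):
        cov, trait, focal, pool = setup
        a = permutation_null(focal, trait, cov, pool, n_perm=200, seed=5)
        b = permutation_null(focal, trait, cov, pool, n_perm=200, seed=5)
        assert a.empirical_p == b.empirical_p
        np.testing.assert_array_equal(a.null_pvalues, b.null_pvalues)

    def test_self_in_pool_counts_in_k(self, setup):
        cov, trait, focal, _ = setup
        res = permutation_null(
            focal, trait, cov, {"self": focal}, n_perm=50, scheme="resample", seed=0
        )
        # every permutation re-draws the focal vector itself: p equal, k = n
        assert res.empirical_p == 1.0
        np.testing.assert_allclose(res.null_pvalues, res.observed_p)

    def test_boundary_conventions(self, setup):
        cov, trait, focal, pool = setup
        # make the focal association essentially perfect
        strong = {s: 10.0 * trait[s] for s in trait}
        res = permutation_null(strong, trait, cov, pool, n_perm=100, seed=1)
        assert res.empirical_p == 0.0
        assert res.empirical_p_plus1 == pytest.approx(1 / 101)

    def test_empty_pool_rejected(self, setup):
        cov, trait, focal, _ = setup
        with pytest.raises(ValueError, match="pool"):
            permutation_null(focal, trait, cov, {}, n_perm=10)


class TestRankFocal:
    def make_controls(self, values, trait="brain"):
        return [
            GeneEvolSummary(gene_id=f"c{i}", marginal_r={trait: v})
            for i, v in enumerate(values)
        ]

    def test_direct_count(self):
        controls = self.make_controls(np.linspace(-0.5, 0.35, 124))
        focal = GeneEvolSummary(gene_id="f", marginal_r={"brain": 0.4})
        assert rank_focal(controls, focal, "brain") == pytest.approx(100 / 125)

    def test_worst_rank(self):
        controls = self.make_controls([0.1, 0.2, 0.3])
        focal = GeneEvolSummary(gene_id="f", marginal_r={"brain": 0.0})
        assert rank_focal(controls, focal, "brain") == pytest.approx(100.0)

    def test_fifth_of_125(self):
        vals = list(np.linspace(-0.9, 0.3, 120)) + [0.5, 0.6, 0.7, 0.8]
        focal = GeneEvolSummary(gene_id="f", marginal_r={"brain": 0.4})
        assert rank_focal(self.make_controls(vals), focal, "brain") == pytest.approx(4.0)

    @given(
        st.floats(min_value=0.01, max_value=5.0),
        st.floats(min_value=-3.0, max_value=3.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_invariant_to_monotone_transform(self, scale, shift):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal(30)
        focal_val = 0.7
        controls = self.make_controls(vals)
        focal = GeneEvolSummary(gene_id="f", marginal_r={"brain": focal_val})
        base = rank_focal(controls, focal, "brain")
        controls_t = self.make_controls(scale * vals + shift)
        focal_t = GeneEvolSummary(
            gene_id="f", marginal_r={"brain": scale * focal_val + shift}
        )
        assert rank_focal(controls_t, focal_t, "brain") == base


class TestTracePostprocessing:
    def test_burn_in_removal(self, tmp_path):
        df = pd.DataFrame({"r_brain": np.arange(10_000, dtype=float)})
        p = tmp_path / "run1.trace"
        df.to_csv(p, sep="\t", index=False)
        runs, pooled = parse_coevol_trace([p], burn_in=1000)
        assert len(runs[0]) == 9000
        assert runs[0]["r_brain"].iloc[0] == 1000

    def test_burn_in_exceeding_rows_errors(self, tmp_path):
        p = tmp_path / "r.trace"
        pd.DataFrame({"a": [1.0, 2.0]}).to_csv(p, sep="\t", index=False)
        with pytest.raises(ValueError, match="empty posterior"):
            parse_coevol_trace([p], burn_in=5)

    def test_inconsistent_headers_error(self, tmp_path):
        p1, p2 = tmp_path / "1.trace", tmp_path / "2.trace"
        pd.DataFrame({"a": np.arange(10.0)}).to_csv(p1, sep="\t", index=False)
        pd.DataFrame({"b": np.arange(10.0)}).to_csv(p2, sep="\t", index=False)
        with pytest.raises(ValueError, match="header"):
            parse_coevol_trace([p1, p2], burn_in=2)

    def test_constant_chain_posterior_mean(self, tmp_path):
        p = tmp_path / "c.trace"
        pd.DataFrame({"a": np.full(50, 3.25)}).to_csv(p, sep="\t", index=False)
        runs, pooled = parse_coevol_trace([p], burn_in=10)
        mean, pp, disp = posterior_summary(pooled["a"])
        assert mean == pytest.approx(3.25)


class TestPosteriorSummary:
    def test_all_positive(self):
        mean, pp, disp = posterior_summary([0.1, 0.2, 0.3])
        assert pp == 1.0 and disp == 1.0

    def test_symmetric(self):
        mean, pp, disp = posterior_summary([-0.4, 0.4, -0.1, 0.1])
        assert pp == 0.5 and disp == 0.5

    def test_mixed_sample(self):
        mean, pp, disp = posterior_summary([-0.1, -0.2, 0.3, 0.4, 0.5])
        assert pp == pytest.approx(0.6)
        assert disp == pytest.approx(0.6)
        assert mean > 0


class TestConvergence:
    def test_identical_runs_zero_reldiff(self):
        rng = np.random.default_rng(0)
        run = pd.DataFrame({"a": rng.standard_normal(500)})
        rep = convergence_diagnostics([run, run.copy()])
        assert rep.loc["a", "reldiff"] == 0.0
        assert rep.loc["a", "passed"]

    def test_iid_ess_near_n(self):
        rng = np.random.default_rng(12)
        vals = [effective_sample_size(rng.standard_normal(1000)) for _ in range(20)]
        assert 800 <= np.mean(vals) <= 1200

    def test_ar1_ess_matches_closed_form(self):
        rho, n = 0.9, 1000
        expected = n * (1 - rho) / (1 + rho)  # ~52.6
        rng = np.random.default_rng(77)
        vals = []
        for _ in range(30):
            x = np.empty(n)
            x[0] = rng.standard_normal() / np.sqrt(1 - rho**2)
            for i in range(1, n):
                x[i] = rho * x[i - 1] + rng.standard_normal()
            vals.append(effective_sample_size(x))
        assert abs(np.mean(vals) - expected) <= 0.4 * expected

    def test_divergent_runs_fail(self):
        rng = np.random.default_rng(5)
        a = pd.DataFrame({"a": rng.standard_normal(400)})
        b = pd.DataFrame({"a": rng.standard_normal(400) + 5.0})
        rep = convergence_diagnostics([a, b])
        assert not rep.loc["a", "passed"]

    def test_single_run_reldiff_unavailable(self):
        rng = np.random.default_rng(6)
        rep = convergence_diagnostics([pd.DataFrame({"a": rng.standard_normal(400)})])
        assert np.isnan(rep.loc["a", "reldiff"])
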