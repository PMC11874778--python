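import itertools

import numpy as np
import pytest
from scipy import special

from lupine.inference import (
    bootstrap_pvalue_ci,
    infer_network_single,
    partial_correlation,
    permutation_pvalue,
    residualize,
)
from lupine.inference import infer_network_longitudinal
from lupine.io import CountMatrix, TimeSeriesStudy
from lupine.latent import pca_first_component
from lupine.preprocess import standardized_log


def _t_pvalue_oracle(t_stat, df):
    """Two-sided t p-value through the regularized incomplete beta function
    (independent of scipy.stats.t)."""
    x = df / (df + t_stat**2)
    return special.betainc(df / 2.0, 0.5, x)


class TestResidualize:
    def test_perfect_fit_gives_zero_residuals(self, rng):
        u = rng.normal(size=15)
        y = np.exp(u)  # log(y) = u exactly
        e = residualize(y, u)
        np.testing.assert_allclose(e, 0.0, atol=1e-10)

    def test_orthogonal_covariate_leaves_centred_logs(self, rng):
        y = rng.poisson(40, size=20).astype(float) + 1
        logy = np.log(y)
        # build a covariate orthogonal to both the intercept and log(y)
        u = rng.normal(size=20)
        u -= u.mean()
        u -= (u @ (logy - logy.mean())) / ((logy - logy.mean()) @ (logy - logy.mean())) * (
            logy - logy.mean()
        )
        e = residualize(y, u)
        np.testing.assert_allclose(e, logy - logy.mean(), atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        n = 20
        y = rng.poisson(30, size=n).astype(float) + 1
        u = rng.normal(size=n)
        lib = rng.poisson(1000, size=n).astype(float)
        e = residualize(y, u, offset=np.log(lib))
        Z = np.column_stack([np.ones(n), u, np.log(lib)])
        beta = np.linalg.inv(Z.T @ Z) @ Z.T @ np.log(y)
        np.testing.assert_allclose(e, np.log(y) - Z @ beta, atol=1e-10)

    def test_residuals_orthogonal_to_regressors(self, rng):
        n = 25
        y = rng.poisson(20, size=n).astype(float) + 1
        u = rng.normal(size=n)
        off = rng.normal(size=n)
        e = residualize(y, u, offset=off)
        assert abs(e.sum()) < 1e-8
        assert abs(e @ u) < 1e-8
        assert abs(e @ off) < 1e-8

    def test_constant_covariate_dropped_with_warning(self, rng):
        y = rng.poisson(20, size=10).astype(float) + 1
        with pytest.warns(UserWarning, match="constant covariate"):
            e = residualize(y, np.full(10, 3.0))
        np.testing.assert_allclose(e, np.log(y) - np.log(y).mean(), atol=1e-12)


class TestPartialCorrelation:
    def test_identical_residuals_give_pi_one(self, rng):
        e = rng.normal(size=10)
        pc = partial_correlation(e, e)
        assert pc.pi == pytest.approx(1.0)
        assert pc.p_value == pytest.approx(0.0)

    def test_zero_correlation_gives_p_one(self):
        e_i = np.array([1.0, -1.0, 1.0, -1.0])
        e_j = np.array([1.0, 1.0, -1.0, -1.0])
        pc = partial_correlation(e_i, e_j)
        assert pc.t_stat == pytest.approx(0.0, abs=1e-12)
        assert pc.p_value == pytest.approx(1.0)

    def test_formula_and_p_value_against_beta_oracle(self):
        # pi = 0.5, n = 25: t = 0.5 * sqrt(23 / 0.75)
        n, pi = 25, 0.5
        t_expected = pi * np.sqrt((n - 2) / (1 - pi**2))
        # build residual vectors with exactly that correlation
        rng = np.random.default_rng(3)
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        a -= a.mean(); b -= b.mean()
        b -= (b @ a) / (a @ a) * a
        a /= np.linalg.norm(a); b /= np.linalg.norm(b)
        e_j = pi * a + np.sqrt(1 - pi**2) * b
        pc = partial_correlation(a, e_j)
        assert pc.pi == pytest.approx(pi, abs=1e-12)
        assert pc.t_stat == pytest.approx(t_expected, rel=1e-10)
        assert pc.df == n - 2
        assert pc.p_value == pytest.approx(_t_pvalue_oracle(t_expected, n - 2), abs=1e-10)

    def test_p_monotone_decreasing_in_abs_pi(self):
        n = 20
        rng = np.random.default_rng(5)
        a = rng.normal(size=n); a -= a.mean(); a /= np.linalg.norm(a)
        b = rng.normal(size=n); b -= b.mean()
        b -= (b @ a) * a; b /= np.linalg.norm(b)
        ps = []
        for pi in (0.1, 0.3, 0.5, 0.7, 0.9):
            pc = partial_correlation(a, pi * a + np.sqrt(1 - pi**2) * b)
            ps.append(pc.p_value)
        assert all(x > y for x, y in zip(ps, ps[1:]))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            partial_correlation(np.zeros(8), np.arange(8.0))


def _poisson_table(rng, n=30, p=10, lam=30):
    counts = rng.poisson(lam, size=(n, p)).astype(float)
    counts[:, counts.sum(axis=0) == 0] = 1
    return CountMatrix(
        counts, [f"s{i}" for i in range(n)], [f"t{j}" for j in range(p)]
    )


class TestInferNetworkSingle:
    def test_alpha_zero_gives_empty_network(self, rng):
        net, _ = infer_network_single(_poisson_table(rng), alpha=0.0)
        assert net.n_edges == 0

    def test_duplicated_taxon_pair_detected(self, rng):
        counts = rng.poisson(50, size=(30, 8)).astype(float) + 1
        counts[:, 1] = counts[:, 0]  # identical columns
        table = CountMatrix(counts, [f"s{i}" for i in range(30)],
                            [f"t{j}" for j in range(8)])
        net, st = infer_network_single(table, alpha=0.05)
        assert net.adjacency[0, 1] == 1
        assert st.p_values[0, 1] < 1e-6

    def test_untested_taxa_isolated_with_missing_stats(self, rng):
        table = _poisson_table(rng, n=25, p=8)
        mask = np.ones(8, dtype=bool)
        mask[[2, 5]] = False
        net, st = infer_network_single(table, tested_mask=mask)
        assert not net.adjacency[2].any() and not net.adjacency[:, 5].any()
        assert np.isnan(st.p_values[2]).all()
        assert np.isnan(st.partial_corr[:, 5]).all()

    def test_lowering_alpha_never_adds_edges(self, rng):
        table = _poisson_table(rng, n=40, p=12)
        net_hi, _ = infer_network_single(table, alpha=0.10)
        net_lo, _ = infer_network_single(table, alpha=0.01)
        assert ((net_lo.adjacency == 1) <= (net_hi.adjacency == 1)).all()

    def test_taxon_relabeling_equivariance(self, rng):
        table = _poisson_table(rng, n=30, p=9)
        perm = rng.permutation(9)
        permuted = CountMatrix(
            table.values[:, perm],
            table.sample_ids,
            [table.taxon_ids[k] for k in perm],
            library_sizes=table.library_sizes,
        )
        net1, _ = infer_network_single(table)
        net2, _ = infer_network_single(permuted)
        np.testing.assert_array_equal(net1.adjacency[np.ix_(perm, perm)], net2.adjacency)

    def test_constant_offset_changes_nothing(self, rng):
        table = _poisson_table(rng, n=30, p=8)
        _, st_lib = infer_network_single(table)
        const = CountMatrix(
            table.values, table.sample_ids, table.taxon_ids,
            library_sizes=np.full(30, 500.0),
        )
        # a constant log-library covariate is absorbed by the intercept
        _, st_const = infer_network_single(const)
        _, st_none = infer_network_single(table, offset="none")
        np.testing.assert_allclose(st_const.p_values, st_none.p_values, atol=1e-10)

    def test_exact_per_pair_close_to_shortcut(self, rng):
        table = _poisson_table(rng, n=30, p=10)
        _, st_fast = infer_network_single(table)
        _, st_exact = infer_network_single(table, exact_per_pair=True)
        iu = np.triu_indices(10, 1)
        r = np.corrcoef(st_fast.partial_corr[iu], st_exact.partial_corr[iu])[0, 1]
        assert r > 0.95


class TestInferNetworkLongitudinal:
    def _study(self, rng, n=25, p=8, T=4):
        tables = [
            _poisson_table(rng, n=n, p=p) for _ in range(T)
        ]
        subjects = [f"s{i}" for i in range(n)]
        for t, tab in enumerate(tables):
            tab.sample_ids = [f"{s}_t{t}" for s in subjects]
        return TimeSeriesStudy(tables, [str(t) for t in range(T)], "g", subjects)

    def test_first_time_point_rejected(self, rng):
        with pytest.raises(ValueError, match="prior time point"):
            infer_network_longitudinal(self._study(rng), t=0)

    def test_window_covering_all_past_equals_all_past(self, rng):
        study = self._study(rng, T=4)
        net_a, st_a = infer_network_longitudinal(study, t=3, history="all_past")
        net_b, st_b = infer_network_longitudinal(study, t=3, history=3)
        np.testing.assert_array_equal(net_a.adjacency, net_b.adjacency)
        np.testing.assert_allclose(st_a.p_values, st_b.p_values, atol=1e-12,
                                   equal_nan=True)

    def test_identical_tables_close_to_single_time(self, rng):
        """With every block identical, the PLS component reduces to the PCA
        component, so the longitudinal network matches the single-time one."""
        table = _poisson_table(rng, n=30, p=8)
        subjects = [f"s{i}" for i in range(30)]
        tabs = []
        for t in range(2):
            tab = CountMatrix(
                table.values.copy(), [f"{s}_t{t}" for s in subjects],
                table.taxon_ids, library_sizes=table.library_sizes,
            )
            tabs.append(tab)
        study = TimeSeriesStudy(tabs, ["0", "1"], "g", subjects)
        net_l, _ = infer_network_longitudinal(study, t=1)
        net_s, _ = infer_network_single(table)
        np.testing.assert_array_equal(net_l.adjacency, net_s.adjacency)

    def test_window_one_uses_pls(self, rng):
        study = self._study(rng, T=4)
        net, st = infer_network_longitudinal(study, t=3, history=1)
        assert net.mode == "longitudinal"
        assert st.df == study.n_subjects - 2


class TestBootstrap:
    def test_intervals_ordered_and_in_unit_range(self, rng):
        table = _poisson_table(rng, n=25, p=6)
        lo, hi = bootstrap_pvalue_ci(table, B=100, seed=0)
        iu = np.triu_indices(6, 1)
        assert ((lo[iu] >= 0) & (hi[iu] <= 1)).all()
        assert (lo[iu] <= hi[iu] + 1e-12).all()

    def test_duplicated_taxa_interval_collapses_to_zero(self, rng):
        counts = rng.poisson(60, size=(25, 6)).astype(float) + 1
        counts[:, 1] = counts[:, 0]
        table = CountMatrix(counts, [f"s{i}" for i in range(25)],
                            [f"t{j}" for j in range(6)])
        lo, hi = bootstrap_pvalue_ci(table, B=100, seed=1)
        assert hi[0, 1] < 1e-6

    def test_reproduces_independent_resampling_oracle(self, rng):
        """Same seed stream, independently coded resampling loop."""
        table = _poisson_table(rng, n=20, p=5)
        B = 100
        lo, hi = bootstrap_pvalue_ci(table, B=B, seed=7)
        oracle_rng = np.random.default_rng(7)
        ps = []
        while len(ps) < B:
            idx = oracle_rng.integers(0, 20, size=20)
            try:
                _, st = infer_network_single(table.reorder_samples(idx))
            except (ValueError, np.linalg.LinAlgError):
                continue
            ps.append(st.p_values)
        stack = np.stack(ps)
        np.testing.assert_allclose(lo, np.nanquantile(stack, 0.025, axis=0),
                                   atol=1e-12, equal_nan=True)
        np.testing.assert_allclose(hi, np.nanquantile(stack, 0.975, axis=0),
                                   atol=1e-12, equal_nan=True)


class TestPermutationPvalue:
    def test_identity_pair_gets_minimal_p(self, rng):
        e = rng.normal(size=10)
        p = permutation_pvalue(e, e, n_perm=200, seed=0)
        # only coincidental permutations can tie |r| = 1
        assert p <= 5 / 201

    def test_sampled_close_to_exhaustive_at_n5(self, rng):
        e_i = rng.normal(size=5)
        e_j = rng.normal(size=5)
        r_obs = abs(np.corrcoef(e_i, e_j)[0, 1])
        hits = sum(
            abs(np.corrcoef(e_i, np.array(perm))[0, 1]) >= r_obs - 1e-12
            for perm in itertools.permutations(e_j)
        )
        exact = hits / 120
        sampled = permutation_pvalue(e_i, e_j, n_perm=20000, seed=1)
        assert sampled == pytest.approx(exact, abs=0.02)

    def test_rank_agreement_with_analytic_p(self, rng):
        """Analytic and permutation p-values order pairs the same way."""
        from scipy.stats import spearmanr

        table = _poisson_table(rng, n=25, p=7)
        _, st = infer_network_single(table)
        X = standardized_log(table)
        factor = pca_first_component(X)
        iu = np.triu_indices(7, 1)
        analytic = st.p_values[iu]
        perm = []
        logy = np.log(np.where(table.values > 0, table.values, 1.0))
        from lupine.latent import masked_component
        from lupine.inference import residualize as _res

        off = np.log(table.library_sizes)
        for i, j in zip(*iu):
            u = masked_component(factor, X, i, j)
            e_i = _res(logy[:, i], u, offset=off, y_is_log=True)
            e_j = _res(logy[:, j], u, offset=off, y_is_log=True)
            perm.append(permutation_pvalue(e_i, e_j, n_perm=2000, seed=11))
        rho = spearmanr(analytic, perm).statistic
        assert rho > 0.9
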