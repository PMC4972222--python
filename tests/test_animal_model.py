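"""REML animal model: design, variance components, h2, tests, G matrix."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ssrherit.animal_model import (
    NotPositiveDefiniteError,
    build_fixed_design,
    g_matrix,
    heritability,
    heritability_ci,
    reml_bivariate,
    reml_univariate,
    variance_z_test,
    wald_f_tests,
)
from ssrherit.synthetic_data import (
    assign_sites,
    simulate_genotypes,
    simulate_traits,
)


def dense_reml_m2l(y, x, m, lam):
    """Independent oracle: -2 REML loglik profiled over Ve, dense algebra."""
    n, p = x.shape
    v = lam * m + np.eye(n)
    vi = np.linalg.inv(v)
    xvx = x.T @ vi @ x
    beta = np.linalg.solve(xvx, x.T @ vi @ y)
    r = y - x @ beta
    rss = float(r @ vi @ r)
    nm = n - p
    return (
        nm * np.log(rss / nm)
        + np.linalg.slogdet(v)[1]
        + np.linalg.slogdet(xvx)[1]
        + nm
        + nm * np.log(2 * np.pi)
    )


@pytest.fixture(scope="module")
def pedigree_pop():
    g, truth = simulate_genotypes(
        n_founders=120, n_descendant_generations=1, clone_rate=0.0, seed=21
    )
    return truth


class TestFixedDesign:
    def test_balanced_layout_has_eight_columns(self):
        ids = [f"i{k}" for k in range(240)]
        factors = assign_sites(ids, seed=0)
        design = build_fixed_design(factors[["transect", "elevation", "microhabitat"]])
        # 1 + 2 (transect) + 1 (elev) + 1 (micro) + 1 (micro:elev) + 2 (micro:transect)
        assert design.p == 8
        assert not design.dropped

    def test_single_site_drops_aliased_columns(self):
        factors = pd.DataFrame(
            {
                "transect": ["J"] * 10,
                "elevation": ["low"] * 10,
                "microhabitat": ["ridge"] * 10,
            }
        )
        with pytest.warns(UserWarning, match="aliased"):
            design = build_fixed_design(factors)
        assert design.p == 1  # intercept only

    def test_row_permutation_invariance(self, pedigree_pop):
        a = pedigree_pop.A
        traits, _ = simulate_traits(a, 0.4, seed=3, ids=pedigree_pop.genet_ids)
        cols = ["transect", "elevation", "microhabitat"]
        perm = np.random.default_rng(0).permutation(len(traits))
        f1 = reml_univariate(
            traits["y1"].to_numpy(), build_fixed_design(traits[cols]), a
        )
        shuffled = traits.iloc[perm]
        f2 = reml_univariate(
            shuffled["y1"].to_numpy(),
            build_fixed_design(shuffled[cols]),
            a[np.ix_(perm, perm)],
        )
        assert f2.va == pytest.approx(f1.va, rel=1e-6, abs=1e-10)
        assert f2.loglik == pytest.approx(f1.loglik, abs=1e-6)


class TestHeritability:
    @pytest.mark.parametrize(
        "va, ve, expected",
        [(10.360, 47.842, 0.178), (0.109, 0.664, 0.141), (0.155, 0.700, 0.181)],
    )
    def test_published_variance_component_ratios(self, va, ve, expected):
        assert heritability(va, ve) == pytest.approx(expected, abs=5e-4)

    def test_edge_cases(self):
        assert heritability(0.0, 1.0) == 0.0
        assert heritability(2.0, 2.0) == 0.5
        with pytest.raises(ValueError):
            heritability(0.0, 0.0)
        with pytest.raises(ValueError):
            heritability(-0.1, 1.0)


class TestRemlUnivariate:
    @pytest.mark.parametrize("seed", range(5))
    def test_optimizer_beats_bruteforce_grid(self, seed):
        """Spectral-profile optimum >= dense 1000-point lambda grid optimum."""
        rng = np.random.default_rng(seed)
        g, truth = simulate_genotypes(
            n_founders=25, n_descendant_generations=1, clone_rate=0.0,
            seed=300 + seed,
        )
        a = truth.A
        n = a.shape[0]
        y = rng.standard_normal(n) + 0.4 * rng.multivariate_normal(
            np.zeros(n), a
        )
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        fit = reml_univariate(y, x, a)
        grid_best = min(
            dense_reml_m2l(y, x, a, lam) for lam in np.geomspace(1e-6, 1e6, 1000)
        )
        grid_best = min(grid_best, dense_reml_m2l(y, x, a, 1e-12))
        assert -2.0 * fit.loglik <= grid_best + 1e-6

    def test_location_and_scale_equivariance(self, pedigree_pop):
        a = pedigree_pop.A
        traits, _ = simulate_traits(a, 0.4, seed=5, ids=pedigree_pop.genet_ids)
        y = traits["y1"].to_numpy()
        x = np.ones((len(y), 1))
        base = reml_univariate(y, x, a)
        shifted = reml_univariate(y + 100.0, x, a)
        scaled = reml_univariate(3.0 * y, x, a)
        assert shifted.va == pytest.approx(base.va, rel=1e-6)
        assert scaled.va == pytest.approx(9.0 * base.va, rel=1e-4)
        assert scaled.h2 == pytest.approx(base.h2, abs=1e-6)

    def test_constant_response_errors(self, pedigree_pop):
        a = pedigree_pop.A
        n = a.shape[0]
        with pytest.raises(ValueError, match="constant response"):
            reml_univariate(np.ones(n), np.ones((n, 1)), a)

    def test_identity_matrix_flagged_unidentifiable(self):
        rng = np.random.default_rng(2)
        n = 60
        fit = reml_univariate(
            rng.standard_normal(n), np.ones((n, 1)), np.eye(n)
        )
        assert not fit.identifiable
        assert np.isnan(fit.h2)

    def test_non_psd_matrix_instructs_near_pd(self):
        rng = np.random.default_rng(3)
        n = 10
        m = np.eye(n)
        m[0, 1] = m[1, 0] = 0.9
        m[0, 2] = m[2, 0] = 0.9
        m[1, 2] = m[2, 1] = -0.5
        with pytest.raises(NotPositiveDefiniteError, match="near_pd"):
            reml_univariate(rng.standard_normal(n), np.ones((n, 1)), m)

    def test_clones_retained_detected(self):
        """Off-diagonal 1 (clonal replicates) must point at clone filtering."""
        rng = np.random.default_rng(4)
        n = 10
        m = np.eye(n)
        m[0, 1] = m[1, 0] = 1.0
        with pytest.raises(ValueError, match="clon"):
            reml_univariate(rng.standard_normal(n), np.ones((n, 1)), m)

    def test_listwise_deletion(self, pedigree_pop):
        a = pedigree_pop.A
        traits, _ = simulate_traits(a, 0.3, seed=6, ids=pedigree_pop.genet_ids)
        y = traits["y1"].to_numpy().copy()
        y[:20] = np.nan
        fit = reml_univariate(y, np.ones((len(y), 1)), a)
        assert fit.n == len(y) - 20


class TestInference:
    def test_ci_delta_vs_parametric_bootstrap(self, pedigree_pop):
        """Delta-method SE of h2 agrees with a parametric bootstrap SE."""
        a = pedigree_pop.A
        n = a.shape[0]
        traits, _ = simulate_traits(a, 0.5, seed=7, ids=pedigree_pop.genet_ids)
        y = traits["y1"].to_numpy()
        x = np.ones((n, 1))
        fit = reml_univariate(y, x, a)
        rng = np.random.default_rng(8)
        la = np.linalg.cholesky(a + 1e-8 * np.eye(n))
        h2s = []
        for _ in range(300):
            sim = (
                np.sqrt(fit.va) * (la @ rng.standard_normal(n))
                + np.sqrt(fit.ve) * rng.standard_normal(n)
            )
            h2s.append(reml_univariate(sim, x, a).h2)
        boot_se = float(np.std(h2s, ddof=1))
        assert fit.h2_se == pytest.approx(boot_se, rel=0.25)
        lo, up = heritability_ci(fit, 0.95)
        assert lo < fit.h2 < up

    def test_z_test_conventions(self, pedigree_pop):
        a = pedigree_pop.A
        n = a.shape[0]
        rng = np.random.default_rng(9)
        # pure-noise trait pushed to the Va = 0 boundary -> p = 0.5
        fit0 = reml_univariate(rng.standard_normal(n), np.ones((n, 1)), a)
        if fit0.va == 0.0:
            assert variance_z_test(fit0) == 0.5
        # Z = 1.645 corresponds to one-sided p ~ 0.05
        assert stats.norm.sf(1.645) == pytest.approx(0.05, abs=1e-3)

    def test_null_type_one_error_is_controlled(self, pedigree_pop):
        """With true h2 = 0 the one-sided Z-test rejects at most ~alpha."""
        a = pedigree_pop.A
        n = a.shape[0]
        rng = np.random.default_rng(10)
        x = np.ones((n, 1))
        rejections = 0
        reps = 60
        for _ in range(reps):
            p = reml_univariate(rng.standard_normal(n), x, a).z_p
            rejections += p < 0.05
        # exact binomial 99.5% upper bound at alpha = 0.05 (boundary makes
        # the test conservative, so the observed rate is usually far lower)
        upper = stats.binom.ppf(0.995, reps, 0.05)
        assert rejections <= upper

    def test_wald_f_matches_classical_anova(self):
        """With Va fixed at 0, the incremental F equals one-way ANOVA F."""
        rng = np.random.default_rng(11)
        levels = np.repeat(["J", "S", "W"], 30)
        y = rng.standard_normal(90) + np.repeat([0.0, 0.5, 1.0], 30)
        factors = pd.DataFrame({"transect": levels})
        design = build_fixed_design(factors, formula="C(transect)")
        fit = reml_univariate(y, design, np.eye(90), lambda_fixed=0.0)
        table = wald_f_tests(fit)
        f_pkg = float(table.loc[table["term"] == "C(transect)", "F"].iloc[0])
        f_ref = stats.f_oneway(y[:30], y[30:60], y[60:]).statistic
        assert f_pkg == pytest.approx(float(f_ref), rel=1e-8)

    def test_aliased_term_reported_dropped(self):
        rng = np.random.default_rng(12)
        factors = pd.DataFrame(
            {"transect": ["J"] * 40, "elevation": ["low"] * 20 + ["high"] * 20,
             "microhabitat": ["ridge", "snowbed"] * 20}
        )
        with pytest.warns(UserWarning):
            design = build_fixed_design(factors)
        fit = reml_univariate(
            rng.standard_normal(40), design, np.eye(40), lambda_fixed=0.0
        )
        notes = dict(zip(fit.wald["term"], fit.wald["note"]))
        assert notes["C(transect)"] == "dropped"


class TestBivariate:
    def test_same_trait_twice_degenerates_to_univariate(self, pedigree_pop):
        a = pedigree_pop.A
        traits, _ = simulate_traits(a, 0.4, seed=13, ids=pedigree_pop.genet_ids)
        y = traits["y1"].to_numpy()
        x = np.ones((len(y), 1))
        uni = reml_univariate(y, x, a)
        biv = reml_bivariate(y, y, x, a)
        assert biv.sigma_a12 == pytest.approx(uni.va, rel=1e-4)

    def test_zero_genetic_correlation_recovered(self, pedigree_pop):
        a = pedigree_pop.A
        x = np.ones((a.shape[0], 1))
        covs = []
        for seed in range(8):
            traits, _ = simulate_traits(
                a, [0.4, 0.4], seed=700 + seed, ids=pedigree_pop.genet_ids,
                genetic_corr=np.eye(2),
            )
            bf = reml_bivariate(
                traits["y1"].to_numpy(), traits["y2"].to_numpy(), x, a
            )
            covs.append(bf.sigma_a12)
        assert np.mean(covs) == pytest.approx(0.0, abs=0.1)

    def test_strong_genetic_correlation_recovered(self, pedigree_pop):
        a = pedigree_pop.A
        x = np.ones((a.shape[0], 1))
        gcorrs = []
        for seed in range(3):
            traits, _ = simulate_traits(
                a, [0.4, 0.4], seed=800 + seed, ids=pedigree_pop.genet_ids,
                genetic_corr=np.array([[1.0, 0.8], [0.8, 1.0]]),
            )
            bf = reml_bivariate(
                traits["y1"].to_numpy(), traits["y2"].to_numpy(), x, a
            )
            gcorrs.append(bf.genetic_correlation)
        assert 0.5 <= np.mean(gcorrs) <= 1.0


class TestGMatrix:
    def test_structure_and_diagonal(self, pedigree_pop):
        a = pedigree_pop.A
        names = [f"t{k}" for k in range(1, 4)]
        traits, _ = simulate_traits(
            a, [0.3, 0.3, 0.3], seed=15, ids=pedigree_pop.genet_ids,
            trait_names=names,
        )
        gm = g_matrix(
            traits[names],
            traits[["transect", "elevation", "microhabitat"]],
            a,
            trait_names=names,
        )
        assert gm.values.shape == (3, 3)
        assert np.allclose(gm.values, gm.values.T)
        for i, t in enumerate(names):
            assert gm.values[i, i] == gm.univariate[t].va

    def test_independent_traits_rarely_significant(self, pedigree_pop):
        a = pedigree_pop.A
        x_factors = None
        n_sig = 0
        reps = 10
        for seed in range(reps):
            traits, _ = simulate_traits(
                a, [0.3, 0.3], seed=900 + seed, ids=pedigree_pop.genet_ids,
                genetic_corr=np.eye(2),
            )
            if x_factors is None:
                x_factors = traits[["transect", "elevation", "microhabitat"]]
            gm = g_matrix(
                traits[["y1", "y2"]], x_factors, a, trait_names=["y1", "y2"]
            )
            p = gm.pvalues[0, 1]
            n_sig += bool(np.isfinite(p) and p < 0.05)
        assert n_sig <= 2
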