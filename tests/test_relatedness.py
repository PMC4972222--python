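"""Relatedness estimators and nearest-PSD conditioning."""

import itertools

import numpy as np
import pytest
from scipy.stats import spearmanr

from ssrherit.genotype_io import AlleleFrequencyTable, GenotypeTable
from ssrherit.relatedness import (
    ESTIMATORS,
    RelatednessMatrix,
    near_pd,
    pairwise_relatedness,
    set_diagonal_unity,
    wang_class_coefficients,
)
from ssrherit.synthetic_data import (
    simulate_founder_frequencies,
    simulate_genotypes,
    simulate_pairs,
)
from conftest import make_pair_table


@pytest.mark.parametrize("estimator", ESTIMATORS)
@pytest.mark.parametrize("p_a", [0.2, 0.5, 0.8])
def test_duplicated_homozygote_gives_unity(estimator, p_a, halfhalf_freqs):
    """A genotype duplicated as a full homozygote has r = 1 (QG: the
    numerator 2 - 2p equals the denominator at every locus)."""
    calls = np.array([[[101, 101]] * 7, [[101, 101]] * 7])
    g = GenotypeTable(["x", "y"], [f"L{j}" for j in range(1, 8)], calls)
    f = AlleleFrequencyTable(
        {f"L{j}": {101: p_a, 103: 1 - p_a} for j in range(1, 8)}
    )
    m = pairwise_relatedness(g, f, estimator)
    assert m.values[0, 1] == pytest.approx(1.0, abs=1e-9)


def test_qg_hand_evaluation_het_pair():
    """QG single-locus value checked against the formula by hand."""
    # x = (101,103), y = (101,105); p = (0.2, 0.3, 0.5)
    g = make_pair_table([(101, 103)], [(101, 105)], n_loci=1)
    f = AlleleFrequencyTable({"L0": {101: 0.2, 103: 0.3, 105: 0.5}})
    m = pairwise_relatedness(g, f, "qg", fill_missing=False)
    # ref x: num = 0.5*(1) - (0.2+0.3) = 0.0; den = 1 + 0 - 0.5 = 0.5
    # ref y: num = 0.5*(1) - (0.2+0.5) = -0.2; den = 1 + 0 - 0.7 = 0.3
    expected = 0.5 * (0.0 / 0.5 + (-0.2) / 0.3)
    assert m.values[0, 1] == pytest.approx(expected, rel=1e-12)


def test_lr_hand_evaluation_het_pair():
    """Lynch-Ritland single-locus value checked by hand, both directions."""
    g = make_pair_table([(101, 103)], [(101, 105)], n_loci=1)
    pa, pb, pc = 0.2, 0.3, 0.5
    f = AlleleFrequencyTable({"L0": {101: pa, 103: pb, 105: pc}})
    m = pairwise_relatedness(g, f, "lr", fill_missing=False)
    # ref x=(a,b): num = pa*(d_bc+d_bd) + pb*(d_ac+d_ad) - 4 pa pb
    num_x = pa * 0 + pb * 1 - 4 * pa * pb
    den_x = (1 + 0) * (pa + pb) - 4 * pa * pb
    num_y = pa * 0 + pc * 1 - 4 * pa * pc
    den_y = (1 + 0) * (pa + pc) - 4 * pa * pc
    expected = 0.5 * (num_x / den_x + num_y / den_y)
    assert m.values[0, 1] == pytest.approx(expected, rel=1e-12)


def test_li_unrelated_expectation_matches_enumeration():
    """E[similarity] over unrelated HWE pairs equals S0 = 2*a2 - a3."""
    rng = np.random.default_rng(0)
    p = rng.dirichlet(np.ones(4))
    alleles = [101, 103, 105, 107]
    pm = dict(zip(alleles, p))
    expect = 0.0
    for (a, b) in itertools.product(alleles, repeat=2):
        for (c, d) in itertools.product(alleles, repeat=2):
            prob = pm[a] * pm[b] * pm[c] * pm[d]
            fx = (float(a in (c, d)) + float(b in (c, d))) / 2.0
            fy = (float(c in (a, b)) + float(d in (a, b))) / 2.0
            expect += prob * 0.5 * (fx + fy)
    a2 = float((p**2).sum())
    a3 = float((p**3).sum())
    assert expect == pytest.approx(2 * a2 - a3, rel=1e-12)


class TestWangClassModel:
    """The genotype-class probabilities behind the Wang estimator."""

    @staticmethod
    def _classify(g1, g2):
        s1, s2 = set(g1), set(g2)
        shared = len(s1 & s2)
        if tuple(sorted(g1)) == tuple(sorted(g2)):
            return 1
        if shared == 1 and (len(s1) == 1) != (len(s2) == 1):
            return 2
        if shared == 1 and len(s1) == 2 and len(s2) == 2:
            return 3
        return 4

    @pytest.mark.parametrize("seed", range(3))
    def test_unrelated_class_probabilities(self, seed):
        """b, d, f match exhaustive enumeration of independent dyads."""
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(4))
        b, c, d, e, f, g = wang_class_coefficients(p)
        probs = {1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0}
        for combo in itertools.product(range(4), repeat=4):
            pr = np.prod(p[list(combo)])
            probs[self._classify(combo[:2], combo[2:])] += pr
        assert probs[1] == pytest.approx(b, rel=1e-10)
        assert probs[2] == pytest.approx(d, rel=1e-10)
        assert probs[3] == pytest.approx(f, rel=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_one_ibd_pair_class_probabilities(self, seed):
        """b+c, d+e, f+g match enumeration of dyads sharing one gene IBD."""
        rng = np.random.default_rng(100 + seed)
        p = rng.dirichlet(np.ones(4))
        b, c, d, e, f, g = wang_class_coefficients(p)
        probs = {1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0}
        # x = (i, j), y = (i, k): i the IBD-shared gene, j, k independent
        for i, j, k in itertools.product(range(4), repeat=3):
            pr = p[i] * p[j] * p[k]
            probs[self._classify((i, j), (i, k))] += pr
        assert probs[1] == pytest.approx(b + c, rel=1e-10)
        assert probs[2] == pytest.approx(d + e, rel=1e-10)
        assert probs[3] == pytest.approx(f + g, rel=1e-10)


@pytest.mark.parametrize("estimator", ESTIMATORS)
def test_estimator_means_on_known_dyads(estimator):
    """Unbiasedness sanity at reduced scale: r ~ 0 (unrelated), ~ 0.5 (PO)."""
    f = simulate_founder_frequencies(seed=11)
    for relationship, target, tol in (
        ("unrelated", 0.0, 0.04),
        ("parent_offspring", 0.5, 0.08),
    ):
        g = simulate_pairs(f, 300, relationship, seed=12)
        m = pairwise_relatedness(g, f, estimator)
        vals = m.values[np.arange(0, 600, 2), np.arange(1, 600, 2)]
        assert np.mean(vals) == pytest.approx(target, abs=tol)


def test_matrix_is_symmetric_with_unit_diagonal():
    g, _ = simulate_genotypes(n_founders=40, clone_rate=0.0, seed=5)
    for est in ESTIMATORS:
        m = pairwise_relatedness(g, estimator=est)
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 1.0)


def test_estimators_rank_correlated_on_mixed_pedigree():
    """All four estimators order pairs consistently (Spearman rho > 0.5)."""
    g, _ = simulate_genotypes(
        n_founders=50, n_descendant_generations=1, clone_rate=0.0, seed=6
    )
    iu = np.triu_indices(g.n_individuals, k=1)
    vecs = {
        est: pairwise_relatedness(g, estimator=est).values[iu]
        for est in ESTIMATORS
    }
    for e1, e2 in itertools.combinations(ESTIMATORS, 2):
        rho = spearmanr(vecs[e1], vecs[e2]).statistic
        assert rho > 0.5, (e1, e2, rho)


def test_unknown_estimator_rejected():
    g, _ = simulate_genotypes(n_founders=5, clone_rate=0.0, seed=0)
    with pytest.raises(ValueError, match="unknown estimator"):
        pairwise_relatedness(g, estimator="ritland")


def test_set_diagonal_unity_leaves_offdiagonal_untouched():
    rng = np.random.default_rng(0)
    v = rng.normal(size=(4, 4))
    v = 0.5 * (v + v.T)
    np.fill_diagonal(v, 0.9)
    m = RelatednessMatrix(list("abcd"), v, "qg")
    out = set_diagonal_unity(m)
    assert np.allclose(np.diag(out.values), 1.0)
    off = ~np.eye(4, dtype=bool)
    assert np.array_equal(out.values[off], v[off])


class TestNearPD:
    def _higham_oracle(self, a, n_iter=2000):
        """Independent alternating projections: clip eigenvalues, reset diag."""
        y = a.copy()
        ds = np.zeros_like(a)
        for _ in range(n_iter):
            r = y - ds
            w, v = np.linalg.eigh(r)
            x = (v * np.clip(w, 0, None)) @ v.T
            ds = x - r
            y = x.copy()
            np.fill_diagonal(y, 1.0)
        return y

    def test_already_pd_is_fixed_point(self):
        a = np.array([[1.0, 0.3], [0.3, 1.0]])
        out = near_pd(RelatednessMatrix(["a", "b"], a, "qg"))
        assert np.max(np.abs(out.values - a)) < 1e-10

    def test_matches_independent_oracle(self):
        a = np.array([[1.0, 1.2], [1.2, 1.0]])
        out = near_pd(RelatednessMatrix(["a", "b"], a, "qg"))
        assert np.max(np.abs(out.values - self._higham_oracle(a))) < 1e-6

    def test_matches_statsmodels_corr_nearest(self):
        from statsmodels.stats.correlation_tools import corr_nearest

        rng = np.random.default_rng(1)
        v = rng.uniform(-0.4, 0.6, size=(8, 8))
        v = 0.5 * (v + v.T)
        np.fill_diagonal(v, 1.0)
        v[0, 1] = v[1, 0] = 1.3  # force indefiniteness
        out = near_pd(RelatednessMatrix([str(i) for i in range(8)], v, "qg"))
        with np.errstate(all="ignore"):
            oracle = np.asarray(corr_nearest(v, threshold=1e-8, n_fact=500))
        assert np.max(np.abs(out.values - oracle)) < 1e-4
        assert out.min_eigenvalue() >= -1e-12

    def test_better_than_one_shot_clipping(self):
        """Frobenius change no worse than naive clip-and-rescale."""
        g, _ = simulate_genotypes(
            n_founders=50, n_descendant_generations=0, clone_rate=0.0, seed=9
        )
        m = pairwise_relatedness(g, estimator="qg")
        v = m.values - 0.06 * np.eye(50)  # push an eigenvalue negative
        np.fill_diagonal(v, 1.0)
        m2 = RelatednessMatrix(list(m.ids), 0.5 * (v + v.T), "qg")
        if m2.min_eigenvalue() >= 0:
            pytest.skip("perturbation did not create a negative eigenvalue")
        out = near_pd(m2)
        w, q = np.linalg.eigh(m2.values)
        naive = (q * np.clip(w, 1e-8, None)) @ q.T
        d = np.sqrt(np.diag(naive))
        naive = naive / np.outer(d, d)
        assert out.min_eigenvalue() >= -1e-10
        assert np.linalg.norm(out.values - m2.values) <= np.linalg.norm(
            naive - m2.values
        ) + 1e-9

    def test_idempotent(self):
        a = np.array([[1.0, 1.2, 0.1], [1.2, 1.0, -0.2], [0.1, -0.2, 1.0]])
        once = near_pd(RelatednessMatrix(list("abc"), a, "qg"))
        twice = near_pd(once)
        assert np.max(np.abs(twice.values - once.values)) < 1e-10
        assert once.psd and twice.psd

    def test_nonconvergence_reports_iterations(self):
        a = np.array([[1.0, 1.2], [1.2, 1.0]])
        with pytest.raises(RuntimeError, match="2 iterations"):
            near_pd(RelatednessMatrix(["a", "b"], a, "qg"), max_iter=2)


def test_missing_pairs_filled_with_zero_and_counted():
    # y shares no typed locus with x and z
    calls = np.array(
        [
            [[101, 103], [0, 0]],
            [[0, 0], [200, 202]],
            [[101, 101], [0, 0]],
        ]
    )
    g = GenotypeTable(["x", "y", "z"], ["L1", "L2"], calls)
    f = AlleleFrequencyTable(
        {"L1": {101: 0.5, 103: 0.5}, "L2": {200: 0.5, 202: 0.5}}
    )
    m = pairwise_relatedness(g, f, "qg")
    assert m.n_filled == 2
    assert m.values[0, 1] == 0.0 and m.values[1, 2] == 0.0
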