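"""Oracle checks for the score statistics: every quantity is compared with
central finite differences of the variant-specific partial log-likelihood
(evaluated by brute force over risk sets) at gamma = 0."""
import numpy as np
import pytest

from famcensor.association import GeneDropper
from famcensor.decomposition import decompose
from famcensor.efficient_scores import (
    compute_efficient_scores,
    efficient_score_matrix,
    score_components,
)
from famcensor.frailty_null import trivial_null_fit
from tests.conftest import make_trio_cohort


def _brute_loglik(eta, g_b, g_w, y, d, gam_b, gam_w, j):
    """Variant-specific Breslow partial log-likelihood, O(n^2) brute force."""
    e = eta + g_b[:, j] * gam_b + g_w[:, j] * gam_w
    th = np.exp(e)
    ll = 0.0
    for i in range(len(y)):
        if d[i]:
            ll += e[i] - np.log(th[y >= y[i]].sum())
    return ll


@pytest.fixture(scope="module")
def random_instance():
    rng = np.random.default_rng(42)
    n, k = 40, 5
    g_w = rng.normal(size=(n, k))
    g_b = rng.normal(size=(n, k))
    y = rng.uniform(1, 30, n)
    d = (rng.random(n) < 0.6).astype(int)
    eta = rng.normal(0, 0.4, n)
    return g_w, g_b, y, d, eta


def test_scores_match_finite_difference_gradient(random_instance):
    g_w, g_b, y, d, eta = random_instance
    c = score_components(g_w, g_b, y, d, np.exp(eta))
    h = 1e-6
    for j in range(g_w.shape[1]):
        uw = (_brute_loglik(eta, g_b, g_w, y, d, 0, h, j)
              - _brute_loglik(eta, g_b, g_w, y, d, 0, -h, j)) / (2 * h)
        ub = (_brute_loglik(eta, g_b, g_w, y, d, h, 0, j)
              - _brute_loglik(eta, g_b, g_w, y, d, -h, 0, j)) / (2 * h)
        assert c["U_w"][:, j].sum() == pytest.approx(uw, rel=1e-6, abs=1e-6)
        assert c["U_b"][:, j].sum() == pytest.approx(ub, rel=1e-6, abs=1e-6)


def test_information_matches_finite_difference_hessian(random_instance):
    g_w, g_b, y, d, eta = random_instance
    c = score_components(g_w, g_b, y, d, np.exp(eta))
    h = 1e-4
    for j in range(g_w.shape[1]):
        f = lambda b, w: _brute_loglik(eta, g_b, g_w, y, d, b, w, j)
        f0 = f(0, 0)
        iww = -(f(0, h) - 2 * f0 + f(0, -h)) / h**2
        ibb = -(f(h, 0) - 2 * f0 + f(-h, 0)) / h**2
        iwb = -(f(h, h) - f(h, -h) - f(-h, h) + f(-h, -h)) / (4 * h**2)
        assert c["I_ww"][j] == pytest.approx(iww, rel=1e-4, abs=1e-4)
        assert c["I_bb"][j] == pytest.approx(ibb, rel=1e-4, abs=1e-4)
        assert c["I_wb"][j] == pytest.approx(iwb, rel=1e-4, abs=1e-4)


def test_efficient_score_matches_hessian_projection(random_instance):
    """Column sums of S_w equal the numerically projected gradient
    (profiling the between-family direction out at gamma = 0)."""
    g_w, g_b, y, d, eta = random_instance
    c = score_components(g_w, g_b, y, d, np.exp(eta))
    esm = efficient_score_matrix(c["U_w"], c["U_b"], c["I_wb"], c["I_bb"])
    h = 1e-4
    for j in range(g_w.shape[1]):
        f = lambda b, w: _brute_loglik(eta, g_b, g_w, y, d, b, w, j)
        uw = (f(0, h) - f(0, -h)) / (2 * h)
        ub = (f(h, 0) - f(-h, 0)) / (2 * h)
        ibb = -(f(h, 0) - 2 * f(0, 0) + f(-h, 0)) / h**2
        iwb = -(f(h, h) - f(h, -h) - f(-h, h) + f(-h, -h)) / (4 * h**2)
        proj = uw - iwb / ibb * ub
        assert esm.S_w[:, j].sum() == pytest.approx(proj, rel=1e-4, abs=1e-5)


def test_column_sum_identity_exact(random_instance):
    g_w, g_b, y, d, eta = random_instance
    c = score_components(g_w, g_b, y, d, np.exp(eta))
    esm = efficient_score_matrix(c["U_w"], c["U_b"], c["I_wb"], c["I_bb"])
    expect = esm.U_w - esm.I_wb / esm.I_bb * esm.U_b
    np.testing.assert_allclose(esm.S_w.sum(axis=0), expect, rtol=1e-12)


def test_cauchy_schwarz_on_information(random_instance):
    g_w, g_b, y, d, eta = random_instance
    c = score_components(g_w, g_b, y, d, np.exp(eta))
    assert np.all(c["I_ww"] >= -1e-12) and np.all(c["I_bb"] >= -1e-12)
    assert np.all(np.abs(c["I_wb"]) <= np.sqrt(c["I_ww"] * c["I_bb"]) + 1e-10)


class TestDegenerateCases:
    def test_self_risk_set_gives_zero(self):
        c = score_components(
            np.array([[1.0]]), np.array([[0.5]]), np.array([5.0]),
            np.array([1]), np.array([1.0]),
        )
        assert c["U_w"][0, 0] == 0.0 and c["I_ww"][0] == 0.0

    def test_two_subject_example(self):
        # theta = 1, both events, Y1 < Y2, G_w column (1, 0):
        # U_w = (1 - 1/2) + (0 - 0) = 0.5; first event's information 0.25
        c = score_components(
            np.array([[1.0], [0.0]]), np.array([[0.0], [0.0]]),
            np.array([1.0, 2.0]), np.array([1, 1]), np.ones(2),
        )
        assert c["U_w"].sum() == pytest.approx(0.5)
        assert c["I_ww"][0] == pytest.approx(0.25)

    def test_constant_column_gives_zero_score(self):
        rng = np.random.default_rng(0)
        n = 20
        g_w = np.full((n, 1), 3.7)
        y = rng.uniform(1, 10, n)
        d = (rng.random(n) < 0.5).astype(int)
        c = score_components(g_w, g_w, y, d, np.ones(n))
        np.testing.assert_allclose(c["U_w"], 0.0, atol=1e-12)

    def test_zero_between_information_skips_correction(self):
        c = score_components(
            np.array([[1.0], [0.0], [2.0]]), np.zeros((3, 1)),
            np.array([1.0, 2.0, 3.0]), np.array([1, 1, 0]), np.ones(3),
        )
        esm = efficient_score_matrix(c["U_w"], c["U_b"], c["I_wb"], c["I_bb"])
        np.testing.assert_allclose(esm.S_w, c["U_w"])


def test_non_event_rows_are_zero(null_trio_cohort):
    decomp = decompose(null_trio_cohort)
    fit = trivial_null_fit(len(decomp.offspring_ids))
    esm = compute_efficient_scores(decomp, fit, null_trio_cohort.phenotypes)
    non_events = null_trio_cohort.phenotypes.event == 0
    np.testing.assert_array_equal(esm.S_w[non_events], 0.0)


def test_permutation_equivariance(random_instance):
    """Reordering subjects consistently permutes the rows of S_w."""
    g_w, g_b, y, d, eta = random_instance
    th = np.exp(eta)
    c1 = score_components(g_w, g_b, y, d, th)
    e1 = efficient_score_matrix(c1["U_w"], c1["U_b"], c1["I_wb"], c1["I_bb"])
    rng = np.random.default_rng(1)
    perm = rng.permutation(len(y))
    c2 = score_components(g_w[perm], g_b[perm], y[perm], d[perm], th[perm])
    e2 = efficient_score_matrix(c2["U_w"], c2["U_b"], c2["I_wb"], c2["I_bb"])
    np.testing.assert_allclose(e2.S_w, e1.S_w[perm], atol=1e-12)


def test_gene_drop_null_score_mean_zero(null_trio_cohort):
    """Over gene-dropped transmissions with phenotypes fixed, each S_w column
    has empirical mean near zero (|mean| < 3 SE)."""
    cohort = null_trio_cohort
    decomp = decompose(cohort)
    fit = trivial_null_fit(len(decomp.offspring_ids))
    pheno = cohort.phenotypes
    dropper = GeneDropper(cohort, decomp)
    rng = np.random.default_rng(3)
    from famcensor.riskset import SurvivalContext

    ctx = SurvivalContext(pheno.time, pheno.event, fit.theta)
    n_drop = 2000
    sums = np.empty((n_drop, len(decomp.variant_ids)))
    for b in range(n_drop):
        g_w = dropper.drop(rng)
        c = score_components(g_w, decomp.G_b, pheno.time, pheno.event, fit.theta, ctx=ctx)
        esm = efficient_score_matrix(c["U_w"], c["U_b"], c["I_wb"], c["I_bb"])
        sums[b] = esm.S_w.sum(axis=0)
    se = sums.std(axis=0, ddof=1) / np.sqrt(n_drop)
    frac_ok = np.mean(np.abs(sums.mean(axis=0)) < 3 * np.maximum(se, 1e-12))
    assert frac_ok > 0.95  # 3 SE criterion per column, allow chance failures


def test_missing_family_cells_excluded():
    """A NaN cell removes that family from the variant's risk sets but the
    other variants are unaffected."""
    rng = np.random.default_rng(2)
    n, k = 30, 3
    g_w = rng.normal(size=(n, k))
    g_b = rng.normal(size=(n, k))
    y = rng.uniform(1, 20, n)
    d = (rng.random(n) < 0.6).astype(int)
    th = np.ones(n)
    g_w_miss = g_w.copy()
    g_w_miss[[3, 7], 1] = np.nan
    c_full = score_components(g_w, g_b, y, d, th)
    c_miss = score_components(g_w_miss, g_b, y, d, th)
    np.testing.assert_allclose(c_miss["U_w"][:, 0], c_full["U_w"][:, 0])
    np.testing.assert_allclose(c_miss["U_w"][:, 2], c_full["U_w"][:, 2])
    # excluded subjects contribute nothing at the affected variant
    assert c_miss["U_w"][3, 1] == 0.0 and c_miss["U_w"][7, 1] == 0.0
    sub = np.delete(np.arange(n), [3, 7])
    c_sub = score_components(g_w[sub][:, 1:2], g_b[sub][:, 1:2], y[sub], d[sub], th[sub])
    assert c_miss["U_w"][:, 1].sum() == pytest.approx(c_sub["U_w"].sum())
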