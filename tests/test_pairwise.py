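import math

import numpy as np
import pytest
from scipy import integrate

from epiflex import (DegeneracyError, beta3, center, centered_variables,
                     encode_pair, fisher_statistic, fit_pair, p_value,
                     residualize_interaction, residualize_phenotype,
                     t_statistic, yule_check)
from conftest import ols_interaction


def test_center_examples():
    assert np.allclose(center([1, 2, 3]), [-1, 0, 1])
    assert np.allclose(center([5.0] * 4), np.zeros(4))
    v = np.array([3.0, -1.0, 7.5])
    assert np.allclose(center(center(v)), center(v))


def test_residualized_interaction_orthogonal_to_loci(hwe_pair):
    g1, g2, p = hwe_pair
    cv = centered_variables(g1, g2, p, "cartesian")
    rI = residualize_interaction(cv)
    scale = np.linalg.norm(rI)
    assert abs(rI @ cv.g_i) < 1e-9 * scale * np.linalg.norm(cv.g_i)
    assert abs(rI @ cv.g_j) < 1e-9 * scale * np.linalg.norm(cv.g_j)


def test_residualize_interaction_identity_cases(rng):
    m = 40
    g1 = rng.binomial(2, 0.5, m).astype(float)
    g2 = rng.binomial(2, 0.5, m).astype(float)
    cv = centered_variables(g1, g2, rng.normal(size=m), "cartesian")
    # I equal to g_i residualizes to (numerically) zero
    cv.I = cv.g_i.copy()
    assert np.allclose(residualize_interaction(cv), 0.0, atol=1e-10)
    # I orthogonal to both loci is returned unchanged
    q, _ = np.linalg.qr(np.column_stack([cv.g_i, cv.g_j, rng.normal(size=m)]))
    ortho = q[:, 2] - q[:, 2].mean()
    ortho -= (ortho @ cv.g_i) / (cv.g_i @ cv.g_i) * cv.g_i
    ortho -= (ortho @ cv.g_j) / (cv.g_j @ cv.g_j) * cv.g_j
    cv.I = ortho
    assert np.allclose(residualize_interaction(cv), ortho, atol=1e-10)


def test_residualize_matches_normal_equations(rng):
    m = 20
    g1 = rng.binomial(2, 0.4, m).astype(float)
    g2 = rng.binomial(2, 0.3, m).astype(float)
    cv = centered_variables(g1, g2, rng.normal(size=m), "xor")
    X = np.column_stack([cv.g_i, cv.g_j])
    coef = np.linalg.solve(X.T @ X, X.T @ cv.I)
    assert np.allclose(residualize_interaction(cv), cv.I - X @ coef, atol=1e-10)
    coef_p = np.linalg.solve(X.T @ X, X.T @ cv.p)
    assert np.allclose(residualize_phenotype(cv), cv.p - X @ coef_p, atol=1e-10)


@pytest.mark.parametrize("encoding", ["cartesian", "xor"])
@pytest.mark.parametrize("seed", range(8))
def test_beta3_and_t_match_full_ols(encoding, seed):
    """The closed forms reproduce the standard regression's interaction
    coefficient and t-value (the dual-route equivalence of the method)."""
    r = np.random.default_rng(seed)
    m = int(r.integers(10, 200))
    g1 = r.binomial(2, 0.35, m).astype(float)
    g2 = r.binomial(2, 0.45, m).astype(float)
    p = 0.1 * g1 + 0.2 * g2 + 0.3 * g1 * g2 + r.normal(size=m)
    try:
        fit = fit_pair(g1, g2, p, encoding)
    except DegeneracyError:
        pytest.skip("degenerate random draw")
    I = encode_pair(g1, g2, encoding)
    b_ols, t_ols = ols_interaction(g1, g2, I, p)
    assert fit.beta3 == pytest.approx(b_ols, rel=1e-8, abs=1e-10)
    assert fit.t_stat == pytest.approx(t_ols, rel=1e-8, abs=1e-10)
    assert fit.df == m - 4


def test_beta3_trivial_cases(rng):
    m = 60
    g1 = rng.binomial(2, 0.5, m).astype(float)
    g2 = rng.binomial(2, 0.5, m).astype(float)
    cv = centered_variables(g1, g2, rng.normal(size=m), "cartesian")
    rI = residualize_interaction(cv)
    # phenotype orthogonal to resid_I -> beta3 = 0
    cv.p -= (cv.p @ rI) / (rI @ rI) * rI
    cv.p -= cv.p.mean()
    assert beta3(cv).beta3 == pytest.approx(0.0, abs=1e-12)
    # p equal to an interaction orthogonal to the loci -> beta3 = 1
    cv2 = centered_variables(g1, g2, rng.normal(size=m), "cartesian")
    cv2.I = residualize_interaction(cv2)
    cv2.p = cv2.I + 1e-3 * rng.normal(size=m)
    cv2.p -= cv2.p.mean()
    assert beta3(cv2).beta3 == pytest.approx(1.0, abs=1e-2)


def test_two_t_forms_and_mse_identity_agree(hwe_pair):
    g1, g2, p = hwe_pair
    cv = centered_variables(g1, g2, p, "cartesian")
    fit = beta3(cv)
    # ratio-of-dot-products form vs beta*sqrt(<I,resid_I>/MSE) form
    assert t_statistic(fit) == pytest.approx(fit.t_stat, rel=1e-10)
    # global-residual inner product equals an explicit residual computation
    X = np.column_stack([cv.g_i, cv.g_j, cv.I])
    b = np.linalg.solve(X.T @ X, X.T @ cv.p)
    resid = cv.p - X @ b
    assert fit.p_resid_ip == pytest.approx(float(cv.p @ resid), rel=1e-10)
    assert fit.p_resid_ip == pytest.approx(float(resid @ resid), rel=1e-10)


def test_fisher_statistic_forms(hwe_pair):
    g1, g2, p = hwe_pair
    fit = fit_pair(g1, g2, p, "xor")
    expected = math.sqrt(fit.df) * fit.r / math.sqrt(1 - fit.r ** 2)
    assert fisher_statistic(fit) == pytest.approx(expected)
    assert math.copysign(1, fisher_statistic(fit)) == math.copysign(1, fit.t_stat)
    # direct substitution: r=0.5, df=96
    fit.r, fit.df = 0.5, 96
    assert fisher_statistic(fit) == pytest.approx(math.sqrt(96) * 0.5 / math.sqrt(0.75))


def test_p_value_against_numerical_integration():
    assert p_value(0.0, 10) == pytest.approx(1.0)
    assert p_value(1e9, 10) == pytest.approx(0.0, abs=1e-12)
    df = 10
    # independent oracle: integrate the t density directly
    const = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    dens = lambda x: const * (1 + x * x / df) ** (-(df + 1) / 2)
    tail, _ = integrate.quad(dens, 2.0, np.inf)
    assert p_value(2.0, df) == pytest.approx(2 * tail, rel=1e-8)
    with pytest.raises(ValueError):
        p_value(1.0, 0)


def test_yule_equivalence_reproduces_beta3(hwe_pair):
    g1, g2, p = hwe_pair
    cv = centered_variables(g1, g2, p, "cartesian")
    fit = beta3(cv)
    rp = residualize_phenotype(cv)
    rI = residualize_interaction(cv)
    assert yule_check(fit, rp, rI) == pytest.approx(fit.beta3, rel=1e-10)
    # homogeneity: scaling the phenotype scales the coefficient
    cv2 = centered_variables(g1, g2, 3.0 * p, "cartesian")
    fit2 = beta3(cv2)
    assert yule_check(fit2, residualize_phenotype(cv2), rI) == pytest.approx(3 * fit.beta3, rel=1e-8)


def test_symmetric_encodings_are_locus_order_invariant(hwe_pair):
    g1, g2, p = hwe_pair
    for enc in ("cartesian", "xor"):
        f12 = fit_pair(g1, g2, p, enc)
        f21 = fit_pair(g2, g1, p, enc)
        assert f12.beta3 == pytest.approx(f21.beta3, rel=1e-10)
        assert f12.t_stat == pytest.approx(f21.t_stat, rel=1e-10)


def test_degenerate_pairs_raise_or_flag(rng):
    m = 50
    g1 = rng.binomial(2, 0.5, m).astype(float)
    p = rng.normal(size=m)
    with pytest.raises(DegeneracyError, match="collinear loci"):
        fit_pair(g1, g1, p, "cartesian")
    mono = np.zeros(m)
    with pytest.raises(DegeneracyError, match="monomorphic"):
        fit_pair(mono, g1, p, "cartesian")
    na = fit_pair(g1, g1, p, "cartesian", on_degenerate="na")
    assert na.degenerate and np.isnan(na.beta3) and "collinear" in na.degenerate_reason


def test_missing_genotypes_are_complete_cased(rng):
    m = 80
    g1 = rng.binomial(2, 0.5, m).astype(float)
    g2 = rng.binomial(2, 0.4, m).astype(float)
    p = rng.normal(size=m)
    g1m = g1.copy()
    g1m[:5] = np.nan
    fit = fit_pair(g1m, g2, p, "cartesian")
    ref = fit_pair(g1[5:], g2[5:], p[5:], "cartesian")
    assert fit.beta3 == pytest.approx(ref.beta3)
    assert fit.df == ref.df == (m - 5) - 4
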