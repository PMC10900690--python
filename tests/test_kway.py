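import numpy as np
import pytest

from epiflex import (DegeneracyError, InsufficientSamplesError, build_Q,
                     fit_kway, fit_pair, kway_beta, sequential_residualize)
from epiflex.kway import subset_order


@pytest.mark.parametrize("k, ncols, n_interactions", [
    (2, 4, 1), (3, 8, 4), (4, 16, 11),
])
def test_Q_dimensions(k, ncols, n_interactions, rng):
    m = 2 ** k + 50
    loci = [rng.binomial(2, 0.5, m).astype(float) for _ in range(k)]
    qm = build_Q(loci, rng.normal(size=m), "cartesian")
    assert qm.Q.shape == (m, ncols)
    assert len(qm.subsets) == n_interactions
    assert qm.subsets[-1] == tuple(range(k))          # full set just before p
    assert np.allclose(qm.Q.mean(axis=0), 0.0, atol=1e-12)


def test_subset_order_is_size_then_lexicographic():
    assert subset_order(3) == [(0, 1), (0, 2), (1, 2), (0, 1, 2)]


def test_sweep_orthogonalizes_columns(rng):
    m = 120
    loci = [rng.binomial(2, 0.4, m).astype(float) for _ in range(3)]
    qm = build_Q(loci, rng.normal(size=m), "cartesian")
    sequential_residualize(qm)
    pred = qm.Q[:, :-1]
    gram = pred.T @ pred
    off = gram - np.diag(np.diag(gram))
    assert np.max(np.abs(off)) < 1e-9 * np.max(np.diag(gram))


def test_orthogonal_columns_unchanged_by_each_other():
    v1 = np.array([1.0, -1.0, 1.0, -1.0])
    v2 = np.array([1.0, 1.0, -1.0, -1.0])
    # embed in a hand-built matrix and sweep the first column
    Q = np.column_stack([v1, v2])
    coef = (v1 @ v2) / (v1 @ v1)
    assert coef == 0.0
    assert np.array_equal(Q[:, 1] - coef * Q[:, 0], v2)


def test_k2_path_equals_pairwise_closed_forms(rng):
    m = 100
    g1 = rng.binomial(2, 0.3, m).astype(float)
    g2 = rng.binomial(2, 0.4, m).astype(float)
    p = 0.3 * g1 * g2 + rng.normal(size=m)
    kf = fit_kway([g1, g2], p, "cartesian")
    pf = fit_pair(g1, g2, p, "cartesian")
    assert kf.beta_full == pytest.approx(pf.beta3, rel=1e-10)
    assert kf.t_stat == pytest.approx(pf.t_stat, rel=1e-10)
    assert kf.df == pf.df


@pytest.mark.parametrize("encoding", ["cartesian", "xor"])
@pytest.mark.parametrize("seed", range(4))
def test_k3_matches_seven_predictor_ols(encoding, seed):
    r = np.random.default_rng(seed)
    m = 100
    loci = [r.binomial(2, 0.5, m).astype(float) for _ in range(3)]
    p = 0.4 * loci[0] * loci[1] * loci[2] + r.normal(size=m)
    qm = build_Q(loci, p, encoding)
    X = qm.Q[:, :-1].copy()
    y = qm.Q[:, -1].copy()
    kf = kway_beta(qm)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = resid @ resid / (m - 7 - 1)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    t_ols = beta[-1] / np.sqrt(cov[-1, -1])
    assert kf.beta_full == pytest.approx(beta[-1], rel=1e-8, abs=1e-10)
    assert kf.t_stat == pytest.approx(t_ols, rel=1e-8, abs=1e-10)
    assert kf.df == m - 8


def test_df_and_insufficient_samples(rng):
    loci = [rng.binomial(2, 0.5, 100).astype(float) for _ in range(3)]
    fit = fit_kway(loci, rng.normal(size=100), "cartesian")
    assert fit.df == 92
    with pytest.raises(InsufficientSamplesError):
        small = [g[:8] for g in loci]
        fit_kway(small, rng.normal(size=8), "cartesian")


def test_phenotype_orthogonal_to_predictors_gives_zero_coefficient(rng):
    m = 100
    loci = [rng.binomial(2, 0.5, m).astype(float) for _ in range(3)]
    qm = build_Q(loci, rng.normal(size=m), "cartesian")
    X = qm.Q[:, :-1].copy()
    y = rng.normal(size=m)
    y_orth = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    y_orth -= y_orth.mean()
    fit = fit_kway(loci, y_orth, "cartesian")
    assert fit.beta_full == pytest.approx(0.0, abs=1e-10)


def test_duplicated_locus_raises_degeneracy(rng):
    m = 100
    g = rng.binomial(2, 0.5, m).astype(float)
    g2 = rng.binomial(2, 0.5, m).astype(float)
    with pytest.raises(DegeneracyError):
        fit_kway([g, g, g2], rng.normal(size=m), "cartesian")


def test_locus_order_invariance_of_full_coefficient(rng):
    m = 150
    loci = [rng.binomial(2, 0.5, m).astype(float) for _ in range(3)]
    p = rng.normal(size=m) + 0.3 * (loci[0] % 2 + loci[1] % 2 + loci[2] % 2) % 2
    ref = fit_kway(loci, p, "xor")
    for perm in [(1, 0, 2), (2, 1, 0), (1, 2, 0)]:
        fit = fit_kway([loci[i] for i in perm], p, "xor")
        assert fit.beta_full == pytest.approx(ref.beta_full, rel=1e-9)
        assert fit.t_stat == pytest.approx(ref.t_stat, rel=1e-9)
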