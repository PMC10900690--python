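"""Matrix-based permutation test for the pairwise interaction T statistic.

The phenotype-independent pieces of the pairwise fit — the interaction term
and its partial residual on the two loci — are computed once per pair.  For
each of K permutations of the centered phenotype, only three dot products
change, so the whole test reduces to a few matrix-vector products against an
m x K permuted-phenotype matrix P.  Columns of P may be processed in chunks
(for memory) without changing any count.

The permutation p-value is the fraction of permutations whose |T| is at
least |T_observed|; an optional add-one small-sample correction
(count+1)/(K+1) is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pairwise import CenteredVariables, _fit_from_geometry, _pair_geometry, center, centered_variables

__all__ = ["PermutationSet", "PermutationResult", "build_permutation_matrix",
           "permutation_test"]


@dataclass
class PermutationSet:
    """m x K matrix whose columns are random permutations of the centered
    phenotype, plus the seed and chunk size that produced it."""

    P: np.ndarray
    K: int
    seed: int
    chunk_size: int = 100


@dataclass
class PermutationResult:
    t_obs: float
    exceed_count: int
    K: int
    p_perm: float
    fit: object = None  # the observed-phenotype PairwiseFit


def build_permutation_matrix(p, K: int, seed: int, chunk_size: int = 100) -> PermutationSet:
    """Draw K uniform random permutations of the centered phenotype.

    Permutations are sampled independently (two columns may coincide; the
    identity is not excluded).  Identical (p, K, seed) give a bitwise
    identical matrix regardless of chunk_size, which only controls how many
    columns downstream tests process at a time.
    """
    if K < 1:
        raise ValueError(f"permutation count K must be >= 1, got {K}")
    p_c = center(np.asarray(p, dtype=float))
    rng = np.random.default_rng(seed)
    m = len(p_c)
    P = np.empty((m, K), dtype=float)
    for k in range(K):
        P[:, k] = p_c[rng.permutation(m)]
    return PermutationSet(P=P, K=K, seed=seed, chunk_size=chunk_size)


def permutation_t_stats(cv: CenteredVariables, perms: PermutationSet) -> np.ndarray:
    """T statistic for every permutation column, via the reused geometry.

    For a permuted phenotype q (already centered): with the pair geometry
    fixed, b3 = <q, resid_I>/<I, resid_I>, <q, resid_p> follows from the two
    locus projections, and <q, resid> = <q, resid_p> - b3 <q, I>, giving
    T = sqrt(n-4) <q, resid_I> / sqrt(<I, resid_I> <q, resid>).
    """
    geom = _pair_geometry(cv)
    P = perms.P
    if P.shape[0] != cv.m:
        raise ValueError(
            f"permutation matrix has {P.shape[0]} rows but the pair has {cv.m} samples"
        )
    m = cv.m
    df = m - 4
    t_all = np.empty(perms.K, dtype=float)
    step = max(int(perms.chunk_size), 1)
    for lo in range(0, perms.K, step):
        B = P[:, lo:lo + step]
        q_residI = geom.resid_I @ B                       # <q, resid_I>
        q_gi = cv.g_i @ B
        q_u = geom.u @ B
        q_q = np.einsum("ij,ij->j", B, B)
        q_residp = q_q - q_gi ** 2 / geom.a - q_u ** 2 / geom.schur
        b3 = q_residI / geom.I_residI_ip
        q_resid = q_residp - b3 * q_residI
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.sqrt(df) * q_residI / np.sqrt(geom.I_residI_ip * q_resid)
        t_all[lo:lo + B.shape[1]] = t
    return t_all


def permutation_test(g_i, g_j, p, encoding, perms: PermutationSet,
                     add_one: bool = False) -> PermutationResult:
    """Permutation p-value for the pairwise interaction T at one locus pair.

    Degenerate permutation columns (non-finite T, a floating-point perfect
    fit) are excluded from the effective K.  ``add_one`` switches the
    estimator from count/K to (count+1)/(K+1).
    """
    cv = centered_variables(g_i, g_j, p, encoding)
    fit = _fit_from_geometry(cv, _pair_geometry(cv))
    t_all = permutation_t_stats(cv, perms)
    ok = np.isfinite(t_all)
    K_eff = int(ok.sum())
    exceed = int(np.sum(np.abs(t_all[ok]) >= abs(fit.t_stat)))
    if add_one:
        p_perm = (exceed + 1) / (K_eff + 1)
    else:
        p_perm = exceed / K_eff if K_eff else float("nan")
    return PermutationResult(t_obs=fit.t_stat, exceed_count=exceed, K=K_eff,
                             p_perm=p_perm, fit=fit)
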