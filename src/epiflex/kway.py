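"""Higher-order (k-way) interaction coefficient via sequential residualization.

The order-k model regresses the centered phenotype on the k centered main
effects plus one encoded interaction column for every subset of loci of size
2..k, i.e. 2^k - 1 predictors.  Only the coefficient of the full k-set
interaction is of interest for epistasis detection.

The algorithm builds a working matrix Q of m samples by 2^k columns —
the k main effects, then subset interactions ordered by size and
lexicographically, with the full-set interaction at column 2^k - 1 and the
phenotype last — and sweeps it in place: each column in order has its
projection removed from every later column.  After the sweep the columns are
mutually orthogonal, and the projection coefficient of the phenotype column
on the residualized full-set interaction column *is* the OLS coefficient of
the order-k interaction.  Beyond Q only a few scalars are kept, so the extra
memory is constant.

For k = 2 this reduces exactly to the pairwise closed forms.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .encodings import encode_tuple_columns, resolve_encoding
from .errors import DegeneracyError, InsufficientSamplesError
from .pairwise import _sq_norm_tol, center, p_value

__all__ = ["KwayModelMatrix", "KwayFit", "subset_order", "build_Q",
           "sequential_residualize", "kway_beta", "kway_t", "fit_kway"]

MAX_K_DEFAULT = 6


def subset_order(k: int) -> list[tuple[int, ...]]:
    """Interaction subsets of {0..k-1} of size >= 2, by size then lexicographic.

    The full set comes last, so its interaction lands at column 2^k - 1 of Q
    (1-based) with the phenotype at column 2^k.
    """
    subsets = []
    for size in range(2, k + 1):
        subsets.extend(itertools.combinations(range(k), size))
    return subsets


@dataclass
class KwayModelMatrix:
    """Working matrix for the order-k model: m x 2^k, all columns centered.

    Column layout (0-based): 0..k-1 main effects, then subset interactions
    per :func:`subset_order`, then the phenotype at 2^k - 1.
    """

    Q: np.ndarray
    k: int
    m: int
    subsets: list[tuple[int, ...]] = field(default_factory=list)
    swept: bool = False
    # Captured at the final sweep step (projection of the phenotype column
    # onto the residualized full-set interaction column v): <p_res, v> and
    # <v, v>.  Needed because the full sweep overwrites the phenotype column
    # with the global residual.
    _p_v: float | None = None
    _v_sq: float | None = None

    @property
    def n_predictors(self) -> int:
        return 2 ** self.k - 1

    @property
    def full_interaction_col(self) -> int:
        return 2 ** self.k - 2

    @property
    def phenotype_col(self) -> int:
        return 2 ** self.k - 1


def build_Q(loci, p, encoding="cartesian", max_k: int = MAX_K_DEFAULT) -> KwayModelMatrix:
    """Assemble and center the model matrix for k loci and a phenotype.

    Subset interactions of size s are encoded with the arity-s form of the
    requested encoding (product for Cartesian, heterozygote parity for XOR),
    applied to raw genotypes before centering.
    """
    loci = [np.asarray(g, dtype=float) for g in loci]
    k = len(loci)
    if k < 2:
        raise ValueError(f"k-way model needs at least 2 loci, got {k}")
    if k > max_k:
        raise ValueError(f"k={k} exceeds the cap of {max_k} (2^k model variables)")
    p = np.asarray(p, dtype=float)
    m = len(p)
    if any(len(g) != m for g in loci):
        raise ValueError("loci and phenotype must all have the same length")
    if m <= 2 ** k:
        raise InsufficientSamplesError(
            f"order-{k} model needs more than 2^{k}={2 ** k} samples, got {m}"
        )
    keep = np.isfinite(p)
    for g in loci:
        keep &= np.isfinite(g)
    loci = [g[keep] for g in loci]
    p = p[keep]
    m = int(keep.sum())
    subsets = subset_order(k)
    Q = np.empty((m, 2 ** k), dtype=float)
    for c, g in enumerate(loci):
        Q[:, c] = center(g)
    for c, s in enumerate(subsets, start=k):
        enc = resolve_encoding(encoding, arity=len(s))
        Q[:, c] = center(encode_tuple_columns([loci[i] for i in s], enc))
    Q[:, -1] = center(p)
    return KwayModelMatrix(Q=Q, k=k, m=m, subsets=subsets)


def sequential_residualize(qm: KwayModelMatrix) -> KwayModelMatrix:
    """In-place sweep: remove each column's projection from all later columns.

    Afterwards the columns are mutually orthogonal (an unnormalized
    Gram-Schmidt of the model matrix).  A predictor column whose residual
    squared norm underflows the degeneracy tolerance raises, naming the
    column — that is a collinearity in the model, not an algorithm failure.
    """
    Q = qm.Q
    ncol = Q.shape[1]
    for c in range(ncol - 1):
        nrm = float(Q[:, c] @ Q[:, c])
        if nrm <= _sq_norm_tol(qm.m, 1.0):
            raise DegeneracyError(f"residual norm of Q column {c} underflowed", nrm)
        if c == qm.full_interaction_col:
            qm._v_sq = nrm
            qm._p_v = float(Q[:, c] @ Q[:, qm.phenotype_col])
        coef = (Q[:, c] @ Q[:, c + 1:]) / nrm
        Q[:, c + 1:] -= np.outer(Q[:, c], coef)
    qm.swept = True
    return qm


@dataclass
class KwayFit:
    """Order-k interaction coefficient and its T test."""

    beta_full: float
    t_stat: float
    df: int
    p_value: float
    k: int


def kway_beta(qm: KwayModelMatrix) -> KwayFit:
    """Sweep Q (if not yet swept) and extract the order-k coefficient + test.

    The coefficient is <p_res, v> / <v, v> where v is the fully residualized
    full-set interaction column and p_res the phenotype column residualized
    on every predictor before v; it equals the order-k OLS coefficient of the
    (2^k - 1)-predictor model.
    """
    pcol = qm.phenotype_col
    Q = qm.Q
    if not qm.swept:
        sequential_residualize(qm)
    if qm._v_sq is None or qm._p_v is None:
        raise DegeneracyError("full-set interaction column was never swept")
    v_sq, p_v = qm._v_sq, qm._p_v
    if v_sq <= _sq_norm_tol(qm.m, 1.0):
        raise DegeneracyError("residualized full-set interaction column", v_sq)
    beta_full = p_v / v_sq
    df = qm.m - qm.n_predictors - 1
    if df < 1:
        raise InsufficientSamplesError(
            f"order-{qm.k} test needs m > {qm.n_predictors + 1} samples, got {qm.m}"
        )
    # Phenotype column now holds the global residual of the full model.
    p_resid_ip = float(Q[:, pcol] @ Q[:, pcol])
    if p_resid_ip <= _sq_norm_tol(qm.m, 1.0):
        raise DegeneracyError("<p, resid> in order-k model (perfect fit)", p_resid_ip)
    t = math.sqrt(df) * p_v / math.sqrt(v_sq * p_resid_ip)
    return KwayFit(beta_full=beta_full, t_stat=t, df=df,
                   p_value=p_value(t, df), k=qm.k)


def kway_t(fit: KwayFit) -> float:
    """The T statistic of the order-k coefficient (already in the fit)."""
    if fit.df < 1:
        raise InsufficientSamplesError("degrees of freedom < 1")
    return fit.t_stat


def fit_kway(loci, p, encoding="cartesian", max_k: int = MAX_K_DEFAULT) -> KwayFit:
    """Convenience: build Q, sweep, and return the order-k fit."""
    return kway_beta(build_Q(loci, p, encoding, max_k=max_k))
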