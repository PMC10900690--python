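"""Closed-form pairwise interaction coefficient and tests.

For a locus pair (g_i, g_j), an encoded interaction I and a quantitative
phenotype p, the model after mean-centering every variable is

    p~ = b1*gi~ + b2*gj~ + b3*I~

and only the interaction coefficient b3 is of interest: it carries the
conditional association between phenotype and interaction given both main
effects.  Rather than solving the full normal equations per pair, b3 is
obtained from partial residuals:

    resid_I = I~  projected off  gi~  and the gi~-residualized gj~
    b3      = <p~, resid_I> / <I~, resid_I>

together with the direct T statistic

    T(b3) = sqrt(n - v - 1) * <p~, resid_I>
            / sqrt(<I~, resid_I> * <p~, resid>)

where v = 3 (two main effects + interaction; the intercept is absorbed by
centering, giving df = n - 4) and the global-residual inner product obeys

    <p~, resid> = <p~, resid_p> - b3 * <p~, resid_I>

(the last factor equals <resid_p, I~>, both partial residuals being
orthogonal to the locus span).

Everything reduces to a handful of vector dot products, which is what makes
exhaustive pair scans with arbitrary interaction encodings cheap.

Degenerate pairs (vanishing residual norms, e.g. an interaction collinear
with its loci, or a perfect fit) are floating-point facts of the data, not
algorithm errors; they raise :class:`DegeneracyError` here and are caught,
logged and reported as NA by the scan driver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .encodings import encode_pair, resolve_encoding
from .errors import DegeneracyError, EmptyInputError, InsufficientSamplesError

__all__ = [
    "CenteredVariables",
    "PairwiseFit",
    "center",
    "centered_variables",
    "residualize_interaction",
    "residualize_phenotype",
    "beta3",
    "t_statistic",
    "fisher_statistic",
    "p_value",
    "yule_check",
    "fit_pair",
]

#: Relative scale below which a squared norm is treated as zero.  The
#: absolute tolerance for a vector v of length m is REL_TOL * m * var(v)
#: (with a floor for identically-zero inputs).
REL_TOL = 1e-12


def _sq_norm_tol(m: int, scale: float) -> float:
    return REL_TOL * m * max(scale, 1e-30)


def center(v) -> np.ndarray:
    """Subtract the mean; idempotent, and maps constants to the zero vector."""
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise EmptyInputError("cannot center an empty vector")
    return v - v.mean()


@dataclass
class CenteredVariables:
    """Mean-centered phenotype, genotypes and interaction for one pair."""

    p: np.ndarray
    g_i: np.ndarray
    g_j: np.ndarray
    I: np.ndarray
    m: int

    def __post_init__(self):
        for name in ("p", "g_i", "g_j", "I"):
            if len(getattr(self, name)) != self.m:
                raise ValueError(f"{name} has length {len(getattr(self, name))}, expected {self.m}")


def centered_variables(g_i, g_j, p, encoding="cartesian") -> CenteredVariables:
    """Encode the interaction on raw genotypes, then center all variables.

    Samples with a missing genotype at either locus or a missing phenotype
    are dropped (complete cases per pair) before centering, so the closed
    forms stay exact.
    """
    enc = resolve_encoding(encoding, arity=2)
    g_i = np.asarray(g_i, dtype=float)
    g_j = np.asarray(g_j, dtype=float)
    p = np.asarray(p, dtype=float)
    I = encode_pair(g_i, g_j, enc)
    keep = np.isfinite(g_i) & np.isfinite(g_j) & np.isfinite(p)
    m = int(keep.sum())
    if m == 0:
        raise EmptyInputError("no complete-case samples for this pair")
    return CenteredVariables(
        p=center(p[keep]), g_i=center(g_i[keep]), g_j=center(g_j[keep]),
        I=center(I[keep]), m=m,
    )


@dataclass
class _PairGeometry:
    """Phenotype-independent quantities for one pair, reusable across
    permutations: the locus Gram data and the interaction partial residual."""

    a: float            # <gi~, gi~>
    u: np.ndarray       # gj~ residualized on gi~
    schur: float        # <gj~, gj~> - <gi~, gj~>^2 / <gi~, gi~>
    resid_I: np.ndarray
    I_residI_ip: float  # <I~, resid_I>


def _pair_geometry(cv: CenteredVariables) -> _PairGeometry:
    g_i, g_j, I = cv.g_i, cv.g_j, cv.I
    a = float(g_i @ g_i)
    if a <= _sq_norm_tol(cv.m, np.var(g_i) if a > 0 else 0.0):
        raise DegeneracyError("<g_i, g_i> (monomorphic first locus)", a)
    b = float(g_i @ g_j)
    c = float(g_j @ g_j)
    schur = c - b * b / a
    if schur <= _sq_norm_tol(cv.m, np.var(g_j)):
        raise DegeneracyError("Schur complement of g_j on g_i (collinear loci)", schur)
    u = g_j - (b / a) * g_i
    resid_I = I - (float(I @ g_i) / a) * g_i - (float(I @ u) / schur) * u
    d_II = float(I @ resid_I)
    if d_II <= _sq_norm_tol(cv.m, np.var(I)):
        raise DegeneracyError("<I, resid_I> (interaction collinear with loci)", d_II)
    return _PairGeometry(a=a, u=u, schur=schur, resid_I=resid_I, I_residI_ip=d_II)


def residualize_interaction(cv: CenteredVariables) -> np.ndarray:
    """Partial residual of the interaction on both loci.

    resid_I = I~ - proj onto gi~ - proj onto (gj~ residualized on gi~);
    orthogonal to both genotype vectors by construction.
    """
    g_i, g_j, I = cv.g_i, cv.g_j, cv.I
    a = float(g_i @ g_i)
    if a <= _sq_norm_tol(cv.m, np.var(g_i) if a > 0 else 0.0):
        raise DegeneracyError("<g_i, g_i> (monomorphic first locus)", a)
    b = float(g_i @ g_j)
    schur = float(g_j @ g_j) - b * b / a
    if schur <= _sq_norm_tol(cv.m, np.var(g_j)):
        raise DegeneracyError("Schur complement of g_j on g_i (collinear loci)", schur)
    u = g_j - (b / a) * g_i
    return I - (float(I @ g_i) / a) * g_i - (float(I @ u) / schur) * u


def residualize_phenotype(cv: CenteredVariables) -> np.ndarray:
    """Partial residual of the phenotype on both loci (resid_p)."""
    g_i, g_j, p = cv.g_i, cv.g_j, cv.p
    a = float(g_i @ g_i)
    if a <= _sq_norm_tol(cv.m, np.var(g_i) if a > 0 else 0.0):
        raise DegeneracyError("<g_i, g_i> (monomorphic first locus)", a)
    b = float(g_i @ g_j)
    schur = float(g_j @ g_j) - b * b / a
    if schur <= _sq_norm_tol(cv.m, np.var(g_j)):
        raise DegeneracyError("Schur complement of g_j on g_i (collinear loci)", schur)
    u = g_j - (b / a) * g_i
    return p - (float(p @ g_i) / a) * g_i - (float(p @ u) / schur) * u


@dataclass
class PairwiseFit:
    """Interaction coefficient and test for one locus pair.

    ``resid_I_ip`` is <I~, resid_I>, ``p_residI_ip`` is <p~, resid_I>,
    ``p_residp_ip`` is <p~, resid_p> and ``p_resid_ip`` is <p~, resid>
    for the global residual of the three-predictor model.
    """

    beta3: float
    resid_I_ip: float
    p_residI_ip: float
    p_residp_ip: float
    p_resid_ip: float
    r: float
    t_stat: float
    df: int
    p_value: float
    degenerate: bool = False
    degenerate_reason: str | None = None

    @classmethod
    def na(cls, m: int, reason: str) -> "PairwiseFit":
        nan = float("nan")
        return cls(nan, nan, nan, nan, nan, nan, nan, max(m - 4, 0), nan,
                   degenerate=True, degenerate_reason=reason)


def beta3(cv: CenteredVariables) -> PairwiseFit:
    """Full pairwise fit from the closed forms (coefficient + T + p)."""
    geom = _pair_geometry(cv)
    return _fit_from_geometry(cv, geom)


def _fit_from_geometry(cv: CenteredVariables, geom: _PairGeometry) -> PairwiseFit:
    p = cv.p
    m = cv.m
    df = m - 4
    if df < 1:
        raise InsufficientSamplesError(f"pairwise model needs m >= 5 samples, got {m}")
    p_residI = float(p @ geom.resid_I)
    b3 = p_residI / geom.I_residI_ip
    # <p~, resid_p> computed from dot products; equals ||resid_p||^2
    p_residp = float(p @ p) - float(p @ cv.g_i) ** 2 / geom.a \
        - float(p @ geom.u) ** 2 / geom.schur
    # Global-residual identity: <p, resid> = <p, resid_p> - b3 <resid_p, I>,
    # and <resid_p, I> = <p, resid_I> because both partial residuals are
    # orthogonal to the locus span.
    p_resid = p_residp - b3 * p_residI
    if p_resid <= _sq_norm_tol(m, np.var(p)):
        raise DegeneracyError("<p, resid> (perfect fit / collinearity)", p_resid)
    t = math.sqrt(df) * p_residI / math.sqrt(geom.I_residI_ip * p_resid)
    if p_residp <= _sq_norm_tol(m, np.var(p)):
        raise DegeneracyError("<p, resid_p> (phenotype collinear with loci)", p_residp)
    r = p_residI / math.sqrt(p_residp * geom.I_residI_ip)
    return PairwiseFit(
        beta3=b3,
        resid_I_ip=geom.I_residI_ip,
        p_residI_ip=p_residI,
        p_residp_ip=p_residp,
        p_resid_ip=p_resid,
        r=r,
        t_stat=t,
        df=df,
        p_value=p_value(t, df),
    )


def t_statistic(fit: PairwiseFit) -> float:
    """Direct T for b3, via T = b3 * sqrt(<I~, resid_I> / MSE).

    MSE = <p~, resid> / (n - v - 1); agrees with the ratio-of-dot-products
    form stored in ``fit.t_stat`` up to floating point.
    """
    if fit.p_resid_ip <= 0:
        raise DegeneracyError("<p, resid> (perfect fit)", fit.p_resid_ip)
    mse = fit.p_resid_ip / fit.df
    return fit.beta3 * math.sqrt(fit.resid_I_ip / mse)


def fisher_statistic(fit: PairwiseFit) -> float:
    """Fisher approximate statistic sqrt(n-v-1) * r / sqrt(1 - r^2)."""
    if not abs(fit.r) < 1:
        raise DegeneracyError("|r| = 1 (perfect partial correlation)", fit.r)
    return math.sqrt(fit.df) * fit.r / math.sqrt(1.0 - fit.r ** 2)


def p_value(t: float, df: int) -> float:
    """Two-sided Student-t tail probability 2*P(T_df >= |t|)."""
    if df < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {df}")
    return float(2.0 * stats.t.sf(abs(t), df))


def yule_check(fit: PairwiseFit, resid_p: np.ndarray, resid_I: np.ndarray) -> float:
    """r * ||resid_p|| / ||resid_I||; equals beta3 by Yule's equivalence."""
    np_sq = float(resid_p @ resid_p)
    nI_sq = float(resid_I @ resid_I)
    if np_sq <= 0 or nI_sq <= 0:
        raise DegeneracyError("residual norm in Yule check", min(np_sq, nI_sq))
    return fit.r * math.sqrt(np_sq) / math.sqrt(nI_sq)


def fit_pair(g_i, g_j, p, encoding="cartesian", on_degenerate="raise") -> PairwiseFit:
    """Fit one locus pair from raw (uncentered, possibly missing) inputs.

    ``on_degenerate="na"`` converts degeneracy errors into an NA fit with
    the reason recorded, which is what scan mode wants.
    """
    cv = centered_variables(g_i, g_j, p, encoding)
    try:
        return beta3(cv)
    except DegeneracyError as err:
        if on_degenerate == "na":
            return PairwiseFit.na(cv.m, str(err))
        raise
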