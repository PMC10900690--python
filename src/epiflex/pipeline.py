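"""Scan pipeline: exhaustive pair/triplet scans, FDR, structure correction,
redundancy pruning, QTL/hub annotation and LD diagnostics.

The result of a scan is an "epistasis table" (a pandas DataFrame) with one
row per tested pair (or triplet): interaction coefficient, T statistic,
degrees of freedom, raw and BH-adjusted p-values, the MLG completeness flag,
and — once annotated — pruning reasons and QTL classifications.

Population structure is handled by the mixed-model trick: every model
variable (phenotype, genotypes, encoded interactions) is premultiplied by a
user-supplied inverse square root of the phenotypic covariance before
centering, turning the generalized least squares problem into the ordinary
one the closed forms solve.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data import GenotypeMatrix
from .encodings import encode_pair, mlg_counts, mlg_filter, resolve_encoding
from .errors import AnnotationError, DegeneracyError, InsufficientSamplesError, UndefinedLDError
from .kway import fit_kway
from .pairwise import CenteredVariables, PairwiseFit, beta3, center, fit_pair

__all__ = [
    "LDStats", "prewhiten", "pairwise_scan", "threeway_scan", "bh_fdr",
    "prune_redundant", "qtl_annotate", "call_hubs", "ld_stats",
    "ld_stats_from_counts", "attach_positions",
]

logger = logging.getLogger("epiflex")

PAIR_COLUMNS = ["locus1", "locus2", "beta", "t_stat", "df", "p_raw", "q_fdr",
                "reject", "mlg_pass", "degenerate_reason"]


def prewhiten(variables: np.ndarray, half_inverse_cov: np.ndarray) -> np.ndarray:
    """Multiply model variables (columns) by the half-inverse covariance."""
    variables = np.asarray(variables, dtype=float)
    W = np.asarray(half_inverse_cov, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"half-inverse covariance must be square, got {W.shape}")
    if variables.shape[0] != W.shape[1]:
        raise ValueError(
            f"variables have {variables.shape[0]} samples but the matrix is {W.shape}"
        )
    return W @ variables


def bh_fdr(p_values, alpha: float = 0.05):
    """Benjamini-Hochberg step-up: (q_values, reject_flags).

    NaN entries (degenerate pairs) are excluded from the family and returned
    as NaN / False.
    """
    p = np.asarray(p_values, dtype=float)
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    rej = np.zeros(p.shape, dtype=bool)
    if ok.any():
        rej_ok, q_ok, _, _ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
        q[ok] = q_ok
        rej[ok] = rej_ok
    return q, rej


def _whitened_cv(gi, gj, p_w, W, encoding) -> CenteredVariables:
    """Centered variables with the half-inverse transform applied to raw
    genotypes and the raw-genotype-encoded interaction alike."""
    I = encode_pair(gi, gj, encoding)
    gi_w = W @ gi
    gj_w = W @ gj
    I_w = W @ I
    return CenteredVariables(p=p_w, g_i=center(gi_w), g_j=center(gj_w),
                             I=center(I_w), m=len(p_w))


def pairwise_scan(G: GenotypeMatrix, p, encoding="cartesian", alpha: float = 0.05,
                  min_mlg_count: int = 0, half_inverse_cov=None) -> pd.DataFrame:
    """Fit every unordered locus pair and BH-correct across the scan.

    Rows are ordered by (i, j) locus index; degenerate pairs are logged and
    reported with NA statistics, excluded from the BH family.  ``mlg_pass``
    records whether all nine MLGs reach ``min_mlg_count`` observations (a
    downstream filter; it does not change the test family).
    """
    enc = resolve_encoding(encoding, arity=2)
    p = np.asarray(p, dtype=float)
    if G.n_samples != len(p):
        raise ValueError("genotypes and phenotype disagree on sample count")
    if G.n_loci < 2:
        raise ValueError("need at least 2 loci to scan pairs")
    W = None
    p_w = None
    if half_inverse_cov is not None:
        W = np.asarray(half_inverse_cov, dtype=float)
        if not (np.isfinite(G.values).all() and np.isfinite(p).all()):
            raise ValueError("structure correction requires complete (no-NaN) data")
        p_w = center(prewhiten(p[:, None], W)[:, 0])
    rows = []
    for i, j in itertools.combinations(range(G.n_loci), 2):
        gi, gj = G.values[:, i], G.values[:, j]
        try:
            if W is None:
                fit = fit_pair(gi, gj, p, enc, on_degenerate="na")
            else:
                fit = beta3(_whitened_cv(gi, gj, p_w, W, enc))
        except (DegeneracyError, InsufficientSamplesError) as err:
            fit = PairwiseFit.na(len(p), str(err))
        if fit.degenerate:
            logger.warning("degenerate pair (%s, %s): %s",
                           G.locus_ids[i], G.locus_ids[j], fit.degenerate_reason)
        counts = mlg_counts(gi, gj)
        rows.append({
            "locus1": G.locus_ids[i], "locus2": G.locus_ids[j],
            "beta": fit.beta3, "t_stat": fit.t_stat, "df": fit.df,
            "p_raw": fit.p_value,
            "mlg_pass": mlg_filter(counts, min_mlg_count),
            "degenerate_reason": fit.degenerate_reason,
        })
    table = pd.DataFrame(rows)
    table["q_fdr"], table["reject"] = bh_fdr(table["p_raw"].to_numpy(), alpha)
    table = table[PAIR_COLUMNS]
    if G.annotation is not None:
        table = attach_positions(table, G.annotation)
    return table


def threeway_scan(G: GenotypeMatrix, p, candidate_loci=None, encoding="cartesian",
                  alpha: float = 0.05) -> pd.DataFrame:
    """Order-3 interaction test over all triplets of a candidate locus set.

    The search is exhaustive over the candidates (no main-effect screening:
    zero main-effect coefficients carry no implication for the interaction
    coefficient, so screening is not statistically justified).
    """
    p = np.asarray(p, dtype=float)
    if candidate_loci is None:
        candidates = list(range(G.n_loci))
    else:
        candidates = [c if isinstance(c, (int, np.integer)) else G.locus_ids.index(c)
                      for c in candidate_loci]
    rows = []
    for i, j, k in itertools.combinations(candidates, 3):
        try:
            fit = fit_kway([G.values[:, i], G.values[:, j], G.values[:, k]],
                           p, encoding)
            row = {"beta": fit.beta_full, "t_stat": fit.t_stat, "df": fit.df,
                   "p_raw": fit.p_value, "degenerate_reason": None}
        except (DegeneracyError, InsufficientSamplesError) as err:
            logger.warning("degenerate triplet (%s, %s, %s): %s",
                           G.locus_ids[i], G.locus_ids[j], G.locus_ids[k], err)
            row = {"beta": np.nan, "t_stat": np.nan, "df": np.nan,
                   "p_raw": np.nan, "degenerate_reason": str(err)}
        row.update(locus1=G.locus_ids[i], locus2=G.locus_ids[j], locus3=G.locus_ids[k])
        rows.append(row)
    table = pd.DataFrame(rows)
    table["q_fdr"], table["reject"] = bh_fdr(table["p_raw"].to_numpy(), alpha)
    cols = ["locus1", "locus2", "locus3", "beta", "t_stat", "df", "p_raw",
            "q_fdr", "reject", "degenerate_reason"]
    return table[cols]


def _positions(table: pd.DataFrame, ann: pd.DataFrame, slot: str):
    ids = table[slot]
    missing = set(ids) - set(ann.index)
    if missing:
        raise AnnotationError(f"loci without chrom/bp annotation: {sorted(missing)[:5]}")
    sub = ann.loc[ids]
    return sub["chrom"].to_numpy(), sub["bp"].to_numpy(dtype=np.int64)


def attach_positions(table: pd.DataFrame, ann: pd.DataFrame) -> pd.DataFrame:
    """Add chrom/bp columns per locus slot and the inter/intra pair class."""
    out = table.copy()
    c1, b1 = _positions(out, ann, "locus1")
    c2, b2 = _positions(out, ann, "locus2")
    out["chrom1"], out["bp1"] = c1, b1
    out["chrom2"], out["bp2"] = c2, b2
    out["pair_class"] = np.where(c1 == c2, "intra", "inter")
    return out


DEFAULT_WINDOW_BP = 10_000_000


def prune_redundant(table: pd.DataFrame, ann: pd.DataFrame,
                    window_bp: int = DEFAULT_WINDOW_BP) -> pd.DataFrame:
    """Flag redundant pairs within a physical window (default 10 Mb).

    Rules, applied in order over surviving rows:

    1. interchromosomal redundancy — both slots chromosome-matched and both
       slot bp differences strictly below the window: the pair with the
       lower FDR-adjusted p-value is retained;
    2. mirror redundancy — same criteria with the slots swapped: the pair
       encountered first (table order) is retained;
    3. intrachromosomal redundancy — same bp criteria among same-chromosome
       pairs, lower q retained;
    4. cis removal — any intrachromosomal pair whose own two loci are closer
       than the window is dropped.

    Rows are kept in the table with ``pruned_reason`` set; filter on its
    being null for the surviving set.
    """
    out = attach_positions(table, ann) if "chrom1" not in table.columns else table.copy()
    n = len(out)
    reason = np.array([None] * n, dtype=object)
    c1 = out["chrom1"].to_numpy()
    c2 = out["chrom2"].to_numpy()
    b1 = out["bp1"].to_numpy(dtype=np.int64)
    b2 = out["bp2"].to_numpy(dtype=np.int64)
    q = out["q_fdr"].to_numpy(dtype=float)
    inter = c1 != c2

    def alive(idx):
        return reason[idx] is None

    # 1. interchromosomal redundancy: keep lower q_fdr
    for i, j in itertools.combinations(range(n), 2):
        if not (inter[i] and inter[j] and alive(i) and alive(j)):
            continue
        if (c1[i] == c1[j] and c2[i] == c2[j]
                and abs(b1[i] - b1[j]) < window_bp and abs(b2[i] - b2[j]) < window_bp):
            drop = i if (q[i] > q[j] or (q[i] == q[j] and i > j)) else j
            reason[drop] = "interchromosomal_redundant"
    # 2. mirror redundancy: keep the first-encountered pair
    for i, j in itertools.combinations(range(n), 2):
        if not (inter[i] and inter[j] and alive(i) and alive(j)):
            continue
        if (c1[i] == c2[j] and c2[i] == c1[j]
                and abs(b1[i] - b2[j]) < window_bp and abs(b2[i] - b1[j]) < window_bp):
            reason[j] = "mirror_redundant"
    # 3. intrachromosomal redundancy: keep lower q_fdr
    for i, j in itertools.combinations(range(n), 2):
        if not ((not inter[i]) and (not inter[j]) and alive(i) and alive(j)):
            continue
        if (c1[i] == c1[j]
                and abs(b1[i] - b1[j]) < window_bp and abs(b2[i] - b2[j]) < window_bp):
            drop = i if (q[i] > q[j] or (q[i] == q[j] and i > j)) else j
            reason[drop] = "intrachromosomal_redundant"
    # 4. cis removal on each surviving intrachromosomal pair
    for i in range(n):
        if (not inter[i]) and alive(i) and abs(b1[i] - b2[i]) < window_bp:
            reason[i] = "cis"
    out["pruned_reason"] = reason
    return out


def qtl_annotate(table: pd.DataFrame, ann: pd.DataFrame, qtls: pd.DataFrame,
                 window_bp: int = DEFAULT_WINDOW_BP):
    """Relabel QTL-proximal loci, collapse nearby non-QTL loci, count events.

    A locus within the window of a QTL (same chromosome, |bp difference| <
    window) takes the QTL's identity; if several QTLs qualify the nearest
    wins.  Non-QTL loci on one chromosome are chained in ascending bp order
    (a locus joins the chain while within the window of its predecessor) and
    every member is replaced by the chain's average position.

    Returns ``(annotated_table, per_locus_counts)`` where the table gains
    ``hub1``/``hub2`` (final locus labels) and ``qtl_class`` in
    {"QTL-QTL", "QTL-nonQTL", "nonQTL-nonQTL"}, and the counts are a Series
    of interaction counts per final locus label (each pair contributes one
    count to each of its two loci).
    """
    out = attach_positions(table, ann) if "chrom1" not in table.columns else table.copy()
    qtl_by_chrom = {}
    for qid, row in qtls.iterrows():
        qtl_by_chrom.setdefault(str(row["chrom"]), []).append((qid, int(row["bp"])))

    loci = {}
    for slot in ("1", "2"):
        for lid, ch, bp in zip(out[f"locus{slot}"], out[f"chrom{slot}"], out[f"bp{slot}"]):
            loci[lid] = (str(ch), int(bp))

    label, is_qtl, final_bp = {}, {}, {}
    for lid, (ch, bp) in loci.items():
        cands = [(abs(bp - qbp), qid, qbp) for qid, qbp in qtl_by_chrom.get(ch, [])
                 if abs(bp - qbp) < window_bp]
        if cands:
            d, qid, qbp = min(cands)
            label[lid], is_qtl[lid], final_bp[lid] = str(qid), True, qbp
        else:
            is_qtl[lid] = False

    # chain-collapse non-QTL loci per chromosome in ascending bp order
    nonqtl = sorted(((ch, bp, lid) for lid, (ch, bp) in loci.items() if not is_qtl[lid]))
    clusters = []
    for ch, bp, lid in nonqtl:
        if clusters and clusters[-1][0] == ch and bp - clusters[-1][1][-1][0] < window_bp:
            clusters[-1][1].append((bp, lid))
        else:
            clusters.append((ch, [(bp, lid)]))
    for ch, members in clusters:
        avg = int(round(np.mean([bp for bp, _ in members])))
        name = f"{ch}:{avg}" if len(members) > 1 else members[0][1]
        for bp, lid in members:
            label[lid], final_bp[lid] = name, avg

    out["hub1"] = [label[l] for l in out["locus1"]]
    out["hub2"] = [label[l] for l in out["locus2"]]
    nq = (np.array([is_qtl[l] for l in out["locus1"]], dtype=int)
          + np.array([is_qtl[l] for l in out["locus2"]], dtype=int))
    out["qtl_class"] = np.select([nq == 2, nq == 1], ["QTL-QTL", "QTL-nonQTL"],
                                 default="nonQTL-nonQTL")
    counts = pd.concat([out["hub1"], out["hub2"]]).value_counts()
    counts.index.name = "locus"
    counts.name = "n_interactions"
    return out, counts


def call_hubs(counts: pd.Series, min_interactions: int = 10) -> pd.Series:
    """Loci meeting the hub threshold, sorted by count (desc) then label."""
    hubs = counts[counts >= min_interactions]
    return hubs.sort_index(kind="stable").sort_values(ascending=False, kind="stable")


@dataclass(frozen=True)
class LDStats:
    """Pairwise linkage disequilibrium: normalized D' and squared correlation."""

    d_prime: float
    r2: float
    d: float
    p_a: float
    p_b: float


def ld_stats_from_counts(counts_3x3, tol: float = 1e-8, max_iter: int = 1000) -> LDStats:
    """D' and r^2 from a 3x3 two-locus genotype count table, by EM.

    Haplotype frequencies are estimated under HWE from unphased diploid
    genotypes: only the double heterozygote is phase-ambiguous, and its mass
    is split between the two phase resolutions at each E-step.
    """
    c = np.asarray(counts_3x3, dtype=float)
    if c.shape != (3, 3) or c.sum() <= 0:
        raise ValueError("need a nonempty 3x3 genotype count table")
    n_hap = 2.0 * c.sum()
    # allele "dosage" frequencies at each locus
    pA = (2 * c[2, :].sum() + c[1, :].sum()) / n_hap
    pB = (2 * c[:, 2].sum() + c[:, 1].sum()) / n_hap
    if pA <= 0 or pA >= 1 or pB <= 0 or pB >= 1:
        raise UndefinedLDError("monomorphic locus: LD undefined")
    # unambiguous haplotype counts; c[1,1] double hets are split by EM
    base_AB = 2 * c[2, 2] + c[2, 1] + c[1, 2]
    base_Ab = 2 * c[2, 0] + c[2, 1] + c[1, 0]
    base_aB = 2 * c[0, 2] + c[1, 2] + c[0, 1]
    base_ab = 2 * c[0, 0] + c[0, 1] + c[1, 0]
    dh = c[1, 1]
    pAB, pAb, paB, pab = pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)
    for _ in range(max_iter):
        denom = pAB * pab + pAb * paB
        w = 0.5 if denom <= 0 else pAB * pab / denom
        new = np.array([base_AB + w * dh, base_Ab + (1 - w) * dh,
                        base_aB + (1 - w) * dh, base_ab + w * dh]) / n_hap
        if np.max(np.abs(new - np.array([pAB, pAb, paB, pab]))) < tol:
            pAB, pAb, paB, pab = new
            break
        pAB, pAb, paB, pab = new
    D = pAB - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = 0.0 if dmax == 0 else float(np.clip(D / dmax, -1.0, 1.0))
    r2 = float(np.clip(D * D / (pA * (1 - pA) * pB * (1 - pB)), 0.0, 1.0))
    return LDStats(d_prime=float(d_prime), r2=float(r2), d=float(D),
                   p_a=float(pA), p_b=float(pB))


def ld_stats(g1, g2) -> LDStats:
    """D' and r^2 for a locus pair from unphased 0/1/2 genotypes."""
    counts = mlg_counts(g1, g2)
    c = np.zeros((3, 3))
    for (a, b), v in counts.counts.items():
        c[a, b] = v
    return ld_stats_from_counts(c)
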