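"""Readers and writers for the plain-text formats the pipeline consumes.

Genotypes arrive either as a plain TSV matrix (header of locus ids, one row
per sample with the sample id in the first column) or as a PLINK ``.raw``
style table (FID/IID/PAT/MAT/SEX/PHENOTYPE prefix columns, then one 0/1/2
column per SNP with a counted-allele suffix such as ``_A``).  Locus ids in
the ``chrN.POS_ALLELE`` / ``chrN:POS`` style are parsed opportunistically
for chromosome and position when no annotation file is given.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, make_annotation

__all__ = ["read_genotypes", "read_phenotype", "read_annotation", "read_qtls",
           "read_matrix", "write_results", "align_phenotype", "parse_locus_id"]

_RAW_PREFIX = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]

_LOCUS_ID_RE = re.compile(r"^(?:chr)?([0-9XYMa-z]+)[.:](\d+)(?:_[ACGT]+)?$", re.IGNORECASE)


def parse_locus_id(locus_id: str):
    """(chrom, bp) from a ``chrN.POS_ALLELE``-style id, or None."""
    m = _LOCUS_ID_RE.match(str(locus_id))
    if m:
        return m.group(1), int(m.group(2))
    return None


def _validate_genotype_frame(df: pd.DataFrame, path) -> np.ndarray:
    values = df.to_numpy()
    numeric = pd.to_numeric(pd.Series(values.ravel()), errors="coerce").to_numpy()
    raw_missing = pd.isna(values.ravel())
    bad = ~raw_missing & np.isnan(numeric)
    if bad.any():
        flat = int(np.flatnonzero(bad)[0])
        r, c = divmod(flat, df.shape[1])
        raise ValueError(
            f"{path}: non-numeric genotype {values.ravel()[flat]!r} at data row "
            f"{r + 1}, locus {df.columns[c]!r}"
        )
    numeric = numeric.reshape(values.shape)
    finite = np.isfinite(numeric)
    out_of_range = finite & ~np.isin(numeric, (0.0, 1.0, 2.0))
    if out_of_range.any():
        r, c = np.argwhere(out_of_range)[0]
        raise ValueError(
            f"{path}: genotype {numeric[r, c]!r} at data row {r + 1}, locus "
            f"{df.columns[c]!r} is not 0/1/2"
        )
    return numeric.astype(float)


def read_genotypes(path) -> GenotypeMatrix:
    """Read a genotype table (plain TSV matrix or PLINK .raw dialect).

    Locus ids are kept verbatim (allele tags included); chromosome/position
    annotation is derived from parseable ids when every id parses.
    """
    df = pd.read_csv(path, sep=r"\s+" , dtype=str)
    cols = list(df.columns)
    if cols[: len(_RAW_PREFIX)] == _RAW_PREFIX:
        sample_ids = df["IID"].tolist()
        geno = df.iloc[:, len(_RAW_PREFIX):]
    else:
        sample_ids = df.iloc[:, 0].tolist()
        geno = df.iloc[:, 1:]
    if geno.shape[1] == 0:
        raise ValueError(f"{path}: no genotype columns found")
    values = _validate_genotype_frame(geno, path)
    locus_ids = list(geno.columns)
    parsed = [parse_locus_id(l) for l in locus_ids]
    ann = None
    if all(p is not None for p in parsed):
        ann = make_annotation(locus_ids, [p[0] for p in parsed], [p[1] for p in parsed])
    return GenotypeMatrix(values=values, sample_ids=[str(s) for s in sample_ids],
                          locus_ids=locus_ids, annotation=ann)


def read_phenotype(path) -> pd.Series:
    """Two-column TSV (sample id, value); a header row is detected."""
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (sample id, value)")
    first_val = pd.to_numeric(df.iloc[0, 1], errors="coerce")
    if pd.isna(first_val):
        df = df.iloc[1:]
    values = pd.to_numeric(df.iloc[:, 1], errors="raise").to_numpy(dtype=float)
    return pd.Series(values, index=df.iloc[:, 0].astype(str).to_numpy(), name="phenotype")


def align_phenotype(G: GenotypeMatrix, pheno: pd.Series):
    """Intersect genotype and phenotype samples; report what was dropped.

    Returns (genotypes, phenotype_vector, dropped_sample_ids) with rows in
    the genotype matrix's order.
    """
    common = [s for s in G.sample_ids if s in pheno.index]
    dropped = sorted(set(G.sample_ids).symmetric_difference(pheno.index))
    if not common:
        raise ValueError("no overlapping sample ids between genotypes and phenotype")
    if len(common) != G.n_samples:
        idx = [G.sample_ids.index(s) for s in common]
        G = GenotypeMatrix(values=G.values[idx], sample_ids=common,
                           locus_ids=G.locus_ids, annotation=G.annotation)
    return G, pheno.loc[common].to_numpy(dtype=float), dropped


def read_annotation(path) -> pd.DataFrame:
    """Locus annotation TSV: locus_id, chrom, bp [, qtl_id]."""
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str, "chrom": str})
    required = {"locus_id", "chrom", "bp"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: annotation needs columns {sorted(required)}")
    return make_annotation(df["locus_id"], df["chrom"], df["bp"],
                           df["qtl_id"] if "qtl_id" in df.columns else None)


def read_qtls(path) -> pd.DataFrame:
    """QTL list TSV: qtl_id, chrom, bp; indexed by qtl_id."""
    df = pd.read_csv(path, sep="\t", dtype={"qtl_id": str, "chrom": str})
    required = {"qtl_id", "chrom", "bp"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: QTL list needs columns {sorted(required)}")
    out = df.set_index("qtl_id")[["chrom", "bp"]]
    out["bp"] = out["bp"].astype(np.int64)
    return out


def read_matrix(path) -> np.ndarray:
    """Whitespace-delimited dense matrix (e.g. half-inverse covariance)."""
    return np.loadtxt(path)


def write_results(table: pd.DataFrame, path, float_digits: int = 6) -> None:
    """Write an epistasis table as TSV (floats at 6 significant digits).

    Degenerate rows, if any, are listed in a ``<path>.degenerate.log``
    sidecar for further inspection.
    """
    table.to_csv(path, sep="\t", index=False, float_format=f"%.{float_digits}g")
    if "degenerate_reason" in table.columns:
        bad = table[table["degenerate_reason"].notna()]
        if len(bad):
            with open(f"{path}.degenerate.log", "w") as fh:
                for _, row in bad.iterrows():
                    loci = "/".join(str(row[c]) for c in table.columns
                                    if c.startswith("locus"))
                    fh.write(f"{loci}\t{row['degenerate_reason']}\n")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom1": str, "chrom2": str})
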