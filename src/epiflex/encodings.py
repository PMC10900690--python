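"""Interaction-model encodings and multi-locus genotype (MLG) machinery.

An interaction encoding is a total function from a k-tuple of additive
genotype codes (0/1/2 minor-allele counts) to a real interaction value.  The
two built-ins are

* ``cartesian`` — the arithmetic product of the genotype codes, the default
  in essentially all regression-based epistasis tests;
* ``xor`` — the parity model ``((g1 mod 2) + ... + (gk mod 2)) mod 2``,
  which takes values in {0, 1} and, under full penetrance, is not linearly
  separable and invisible to single-locus analyses.

Arbitrary penetrance tables (for pairwise models: 9 rows) can be supplied as
TSV files with columns ``g1 .. gk value``.

Missing genotypes are NaN-flagged; encoding a tuple with a missing entry
yields a missing interaction value, and downstream fits use complete cases
per locus pair.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyInputError, InvalidGenotypeError

__all__ = [
    "InteractionEncoding",
    "MLGCount",
    "cartesian_encoding",
    "xor_encoding",
    "get_encoding",
    "resolve_encoding",
    "read_encoding_table",
    "encode_pair",
    "encode_tuple_columns",
    "mlg_counts",
    "mlg_filter",
]

_GENOTYPES = (0, 1, 2)


@dataclass(frozen=True)
class InteractionEncoding:
    """A total map from genotype k-tuples in {0,1,2}^k to interaction values."""

    name: str
    table: dict[tuple[int, ...], float]
    arity: int = field(default=0)

    def __post_init__(self):
        arity = self.arity
        if arity == 0:
            arity = len(next(iter(self.table)))
            object.__setattr__(self, "arity", arity)
        if arity < 2:
            raise ValueError(f"encoding arity must be >= 2, got {arity}")
        expected = set(itertools.product(_GENOTYPES, repeat=arity))
        if set(self.table) != expected:
            missing = sorted(expected - set(self.table))[:3]
            raise ValueError(
                f"encoding table for arity {arity} is not total over the "
                f"{3 ** arity} genotype tuples; e.g. missing {missing}"
            )

    def lookup_array(self) -> np.ndarray:
        """The table as a dense (3,)*arity array indexed by genotype codes."""
        arr = np.empty((3,) * self.arity, dtype=float)
        for tup, val in self.table.items():
            arr[tup] = val
        return arr

    def __call__(self, *genotype_vectors) -> np.ndarray:
        return encode_tuple_columns(list(genotype_vectors), self)


def cartesian_encoding(arity: int = 2) -> InteractionEncoding:
    """Product encoding: I = g1 * g2 * ... * gk."""
    table = {
        tup: float(np.prod(tup)) for tup in itertools.product(_GENOTYPES, repeat=arity)
    }
    return InteractionEncoding("cartesian", table, arity)


def xor_encoding(arity: int = 2) -> InteractionEncoding:
    """Parity encoding: I = ((g1 mod 2) + ... + (gk mod 2)) mod 2.

    For two loci this is the classic XOR penetrance model: heterozygosity at
    exactly one locus maps to 1, everything else to 0.  Arities above 2 use
    the natural generalization (parity of the heterozygote count).
    """
    table = {
        tup: float(sum(g % 2 for g in tup) % 2)
        for tup in itertools.product(_GENOTYPES, repeat=arity)
    }
    return InteractionEncoding("xor", table, arity)


_BUILTINS = {"cartesian": cartesian_encoding, "xor": xor_encoding}


def get_encoding(name: str, arity: int = 2) -> InteractionEncoding:
    """Look up a built-in encoding by name for a given arity."""
    try:
        return _BUILTINS[name.lower()](arity)
    except KeyError:
        raise ValueError(
            f"unknown encoding {name!r}; built-ins are {sorted(_BUILTINS)}"
        ) from None


def resolve_encoding(encoding, arity: int = 2) -> InteractionEncoding:
    """Coerce a name or encoding object to an InteractionEncoding of ``arity``.

    Built-in names are instantiated at the requested arity; an explicit
    InteractionEncoding must already match it.
    """
    if isinstance(encoding, str):
        return get_encoding(encoding, arity)
    if isinstance(encoding, InteractionEncoding):
        if encoding.arity != arity:
            if encoding.name in _BUILTINS:
                return get_encoding(encoding.name, arity)
            raise ValueError(
                f"encoding {encoding.name!r} has arity {encoding.arity}, need {arity}"
            )
        return encoding
    raise TypeError(f"cannot interpret {encoding!r} as an interaction encoding")


def read_encoding_table(path, name: str | None = None) -> InteractionEncoding:
    """Read a penetrance-table TSV with columns g1..gk, value.

    The table must be total: every one of the 3^k genotype tuples present
    exactly once.
    """
    df = pd.read_csv(path, sep="\t")
    gcols = [c for c in df.columns if c.lower().startswith("g")]
    if "value" not in df.columns or not gcols:
        raise ValueError(f"{path}: expected columns g1..gk and value")
    table = {}
    for _, row in df.iterrows():
        tup = tuple(int(row[c]) for c in gcols)
        if any(g not in _GENOTYPES for g in tup):
            raise InvalidGenotypeError(tup)
        if tup in table:
            raise ValueError(f"{path}: duplicate genotype tuple {tup}")
        table[tup] = float(row["value"])
    return InteractionEncoding(name or str(path), table, len(gcols))


def _check_genotypes(g: np.ndarray, locus=None) -> np.ndarray:
    g = np.asarray(g, dtype=float)
    if g.size == 0:
        raise EmptyInputError("empty genotype vector")
    finite = np.isfinite(g)
    bad = finite & ~np.isin(g, (0.0, 1.0, 2.0))
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise InvalidGenotypeError(g[idx], locus=locus, sample_index=idx)
    return g


def encode_tuple_columns(genotype_vectors, encoding: InteractionEncoding) -> np.ndarray:
    """Apply an encoding elementwise across k same-length genotype vectors.

    Missing (NaN) genotypes in any input propagate to NaN in the output.
    """
    cols = [_check_genotypes(g, locus=i) for i, g in enumerate(genotype_vectors)]
    if len(cols) != encoding.arity:
        raise ValueError(
            f"encoding {encoding.name!r} has arity {encoding.arity}, got {len(cols)} vectors"
        )
    m = len(cols[0])
    if any(len(c) != m for c in cols):
        raise ValueError("genotype vectors must all have the same length")
    mask = np.logical_and.reduce([np.isfinite(c) for c in cols])
    lut = encoding.lookup_array()
    out = np.full(m, np.nan)
    if mask.any():
        idx = tuple(c[mask].astype(np.intp) for c in cols)
        out[mask] = lut[idx]
    return out


def encode_pair(g1, g2, encoding) -> np.ndarray:
    """Elementwise interaction values for a locus pair under ``encoding``."""
    enc = resolve_encoding(encoding, arity=2)
    return encode_tuple_columns([g1, g2], enc)


@dataclass(frozen=True)
class MLGCount:
    """Counts of the nine two-locus genotype combinations for a locus pair."""

    counts: dict[tuple[int, int], int]

    def __post_init__(self):
        if set(self.counts) != set(itertools.product(_GENOTYPES, repeat=2)):
            raise ValueError("MLGCount requires exactly the 9 biallelic-pair keys")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def min_count(self) -> int:
        return min(self.counts.values())


def mlg_counts(g1, g2) -> MLGCount:
    """Count samples in each of the 9 MLGs, over pairwise-complete cases."""
    a = _check_genotypes(g1, locus=0)
    b = _check_genotypes(g2, locus=1)
    if len(a) != len(b):
        raise ValueError("genotype vectors must have the same length")
    keep = np.isfinite(a) & np.isfinite(b)
    ai = a[keep].astype(int)
    bi = b[keep].astype(int)
    counts = {tup: 0 for tup in itertools.product(_GENOTYPES, repeat=2)}
    flat = ai * 3 + bi
    binned = np.bincount(flat, minlength=9)
    for k, tup in enumerate(itertools.product(_GENOTYPES, repeat=2)):
        counts[tup] = int(binned[tup[0] * 3 + tup[1]])
    return MLGCount(counts)


def mlg_filter(counts: MLGCount, min_count: int) -> bool:
    """True iff every one of the nine MLG counts reaches ``min_count``."""
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    return counts.min_count() >= min_count
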