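"""In-memory containers: genotype matrix with locus metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnnotationError

__all__ = ["GenotypeMatrix", "make_annotation"]


def make_annotation(locus_ids, chroms, bps, qtl_ids=None) -> pd.DataFrame:
    """Annotation table indexed by locus id with chrom, bp (1-based) columns."""
    ann = pd.DataFrame(
        {"chrom": [str(c) for c in chroms], "bp": np.asarray(bps, dtype=np.int64)},
        index=pd.Index(locus_ids, name="locus_id"),
    )
    if (ann["bp"] < 1).any():
        raise ValueError("bp positions must be >= 1")
    if qtl_ids is not None:
        ann["qtl_id"] = qtl_ids
    return ann


@dataclass
class GenotypeMatrix:
    """Samples x loci additive-coded (0/1/2) genotypes with metadata.

    ``values`` is a float array so missing genotypes can be NaN-flagged;
    ``annotation`` (optional) maps locus ids to chromosome and bp position.
    """

    values: np.ndarray
    sample_ids: list[str]
    locus_ids: list[str]
    annotation: pd.DataFrame | None = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D samples x loci array")
        m, n = self.values.shape
        if len(self.sample_ids) != m or len(self.locus_ids) != n:
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples / {len(self.locus_ids)} loci"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    def locus(self, ident) -> np.ndarray:
        """Genotype vector for a locus, by id or integer position."""
        if isinstance(ident, (int, np.integer)):
            return self.values[:, int(ident)]
        return self.values[:, self.locus_ids.index(ident)]

    def locus_position(self, locus_id: str) -> tuple[str, int]:
        """(chrom, bp) for a locus, from the annotation table."""
        if self.annotation is None or locus_id not in self.annotation.index:
            raise AnnotationError(f"locus {locus_id!r} has no chrom/bp annotation")
        row = self.annotation.loc[locus_id]
        return str(row["chrom"]), int(row["bp"])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.locus_ids)
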