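"""Synthetic genotype/phenotype generation with embedded interactions.

The generator emulates the statistical shape of a small GWAS cohort used to
probe interaction-model specificity: independent biallelic loci in
Hardy-Weinberg equilibrium, a continuous phenotype, and pairwise epistatic
signal embedded by rank reassignment.  The embedding ranks the base
phenotype, then for each interacting pair takes a fraction of the samples
and redistributes their phenotype values so that samples with a high encoded
interaction value receive the high values (and low receive low), preserving
the phenotype's multiset; Gaussian noise is added afterwards.  Embedded
pairs are adjacent by default (locus 0 with 1, 2 with 3, ...).

Defaults describe the study conditions exercised throughout the test suite:
2,000 samples, 18 loci at minor-allele frequency 0.3 on synthetic
chromosomes, nine adjacent embedded pairs, a 0.3 reassignment fraction and
residual noise with standard deviation 0.5 (phenotype base sd 1).

What this generator does not emulate: linkage disequilibrium (loci are
independent unless the block-correlated mode is switched on), realistic
allele-frequency spectra, relatedness/population structure, or missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import GenotypeMatrix, make_annotation
from .encodings import encode_pair

__all__ = ["SimConfig", "simulate_genotypes", "embed_interactions",
           "simulate_null", "simulate_dataset", "adjacent_pairs"]


def adjacent_pairs(n_pairs: int) -> list[tuple[int, int]]:
    """Disjoint adjacent index pairs: (0,1), (2,3), ..."""
    return [(2 * i, 2 * i + 1) for i in range(n_pairs)]


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset."""

    m: int = 2000
    n_loci: int = 18
    mafs: float | list[float] = 0.5
    embedded_pairs: list[tuple[int, int]] = field(
        default_factory=lambda: adjacent_pairs(9))
    encoding: str = "xor"
    embed_fraction: float = 0.3
    noise_sd: float = 0.5
    seed: int = 0
    n_chromosomes: int = 5
    locus_spacing_bp: int = 25_000_000
    ld_flip_prob: float | None = None  # block-correlated mode when set

    def maf_vector(self) -> np.ndarray:
        mafs = np.broadcast_to(np.asarray(self.mafs, dtype=float), (self.n_loci,))
        if ((mafs <= 0) | (mafs > 0.5)).any():
            raise ValueError("minor allele frequencies must lie in (0, 0.5]")
        return np.array(mafs)

    def validate_pairs(self):
        for i, j in self.embedded_pairs:
            if not (0 <= i < self.n_loci and 0 <= j < self.n_loci) or i == j:
                raise ValueError(f"embedded pair ({i}, {j}) out of range for "
                                 f"{self.n_loci} loci")


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Independent HWE loci: genotype ~ Binomial(2, MAF) per sample.

    Loci are laid out on ``n_chromosomes`` synthetic chromosomes with
    ``locus_spacing_bp`` between neighbours (wide enough that no two
    distinct loci fall inside the default 10 Mb pruning window).  The
    optional block-correlated mode makes each even/odd locus pair correlated
    by copying with a per-sample flip probability, to exercise LD and
    pruning code.
    """
    mafs = cfg.maf_vector()
    rng = np.random.default_rng(cfg.seed)
    G = rng.binomial(2, mafs[None, :], size=(cfg.m, cfg.n_loci)).astype(float)
    if cfg.ld_flip_prob is not None:
        for i, j in adjacent_pairs(cfg.n_loci // 2):
            flip = rng.random(cfg.m) < cfg.ld_flip_prob
            G[:, j] = np.where(flip, rng.binomial(2, mafs[j], size=cfg.m), G[:, i])
    locus_ids = [f"L{i + 1:03d}" for i in range(cfg.n_loci)]
    per_chrom = -(-cfg.n_loci // cfg.n_chromosomes)  # ceil division
    chroms = [str(1 + i // per_chrom) for i in range(cfg.n_loci)]
    bps = [1 + (i % per_chrom) * cfg.locus_spacing_bp for i in range(cfg.n_loci)]
    ann = make_annotation(locus_ids, chroms, bps)
    sample_ids = [f"S{i + 1:05d}" for i in range(cfg.m)]
    return GenotypeMatrix(values=G, sample_ids=sample_ids, locus_ids=locus_ids,
                          annotation=ann)


def embed_interactions(G: GenotypeMatrix, cfg: SimConfig) -> np.ndarray:
    """Phenotype with rank-reassignment interactions at the configured pairs.

    Starts from a standard-normal base phenotype.  For each embedded pair, a
    random ``embed_fraction`` of the samples have their phenotype values
    redistributed within the subset: the subset's values are sorted and
    handed back in order of the samples' encoded interaction value (ties
    broken at random), so high interaction values get high phenotype values.
    The phenotype multiset is invariant under each reassignment; independent
    N(0, noise_sd^2) noise is added at the end.
    """
    cfg.validate_pairs()
    if not 0 <= cfg.embed_fraction <= 1:
        raise ValueError("embed_fraction must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    p = rng.normal(size=cfg.m)
    n_sub = int(round(cfg.embed_fraction * cfg.m))
    if cfg.embedded_pairs and n_sub > 0:
        # Composite-score alignment: each pair contributes its standardized
        # interaction over its own random portion of samples; the touched
        # samples' phenotype values are then redistributed in one pass in
        # rank order of the composite.  Embedding pairs jointly rather than
        # one after another keeps every pair's signal intact (a sequential
        # reassignment of overlapping subsets would scramble earlier pairs).
        score = np.zeros(cfg.m)
        touched = np.zeros(cfg.m, dtype=bool)
        for i, j in cfg.embedded_pairs:
            subset = rng.choice(cfg.m, size=n_sub, replace=False)
            I = encode_pair(G.values[:, i], G.values[:, j], cfg.encoding)
            Is = I[subset] - I[subset].mean()
            sd = Is.std()
            if sd > 0:
                score[subset] += Is / sd
            touched[subset] = True
        idx = np.flatnonzero(touched)
        order = idx[np.lexsort((rng.random(idx.size), score[idx]))]
        p[order] = np.sort(p[idx])
    if cfg.noise_sd > 0:
        p = p + rng.normal(scale=cfg.noise_sd, size=cfg.m)
    return p


def simulate_null(cfg: SimConfig):
    """Genotypes plus an i.i.d. Gaussian phenotype independent of them."""
    G = simulate_genotypes(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    p = rng.normal(size=cfg.m)
    return G, p


def simulate_dataset(cfg: SimConfig):
    """Genotypes plus a phenotype carrying the configured interactions."""
    G = simulate_genotypes(cfg)
    p = embed_interactions(G, cfg)
    return G, p
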