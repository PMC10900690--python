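"""Exception hierarchy.

Numerical degeneracies (vanishing residual norms, perfect collinearity) are
distinguished from user errors (bad genotype codes, malformed files) so that
scan drivers can log the former per pair and keep going while failing fast on
the latter.
"""


class EpiflexError(Exception):
    """Base class for all package errors."""


class InvalidGenotypeError(EpiflexError, ValueError):
    """A genotype value outside {0, 1, 2} (and not missing-flagged)."""

    def __init__(self, value, locus=None, sample_index=None):
        self.value = value
        self.locus = locus
        self.sample_index = sample_index
        loc = f" at locus {locus!r}" if locus is not None else ""
        smp = f", sample index {sample_index}" if sample_index is not None else ""
        super().__init__(f"invalid genotype value {value!r}{loc}{smp}; expected 0, 1 or 2")


class EmptyInputError(EpiflexError, ValueError):
    """An operation received an empty vector or table."""


class DegeneracyError(EpiflexError, ArithmeticError):
    """A residual (squared) norm underflowed the degeneracy tolerance.

    Carries ``which`` naming the vanishing quantity so the event can be
    logged for further inspection rather than silently swallowed.
    """

    def __init__(self, which, value=None):
        self.which = which
        self.value = value
        detail = f" (value {value:.3e})" if value is not None else ""
        super().__init__(f"degenerate quantity: {which}{detail}")


class InsufficientSamplesError(EpiflexError, ValueError):
    """Too few samples for the requested model's degrees of freedom."""


class AnnotationError(EpiflexError, KeyError):
    """A locus referenced by a result table has no chromosome/position."""


class UndefinedLDError(EpiflexError, ValueError):
    """Linkage-disequilibrium statistics requested for a monomorphic locus."""
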