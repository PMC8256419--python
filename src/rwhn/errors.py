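"""Exception hierarchy for the rwhn package.

Every error raised deliberately by the library derives from :class:`RWHNError`
so callers can catch the package's failures with a single except clause while
letting genuine bugs (TypeError and friends) propagate.
"""


class RWHNError(Exception):
    """Base class for all errors raised by this package."""


# --- io_formats ---------------------------------------------------------


class ParseError(RWHNError):
    """A file could not be parsed (malformed field, bad residue, bad score)."""


class DuplicateSite(ParseError):
    """Two rows of a quant table share the same (accession, position)."""


class EmptyTerm(ParseError):
    """A GMT line declares a term with zero genes."""


class CycleDetected(ParseError):
    """The ontology relations form a directed cycle."""


# --- preprocess ---------------------------------------------------------


class InsufficientData(RWHNError):
    """A condition column has too few observed values to fit a model."""


class MissingData(RWHNError):
    """An operation requiring a complete matrix received missing cells."""


class BadK(RWHNError):
    """Requested cluster count is out of range for the data."""


# --- netbuild -----------------------------------------------------------


class EmptyUniverse(RWHNError):
    """Enrichment requested against an empty gene universe."""


class OrphanSite(RWHNError):
    """A site's host protein is absent from the protein layer."""


class UnknownTerm(RWHNError):
    """A term is missing from the ontology or annotation library."""


# --- rwhn_core ----------------------------------------------------------


class EmptySeeds(RWHNError):
    """The seed set for a random walk is empty."""


class NoConvergence(RWHNError):
    """The walk iteration hit max_iter before the tolerance was reached."""

    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        self.max_iter = max_iter
        super().__init__(
            f"random walk did not converge in {max_iter} iterations "
            f"(final L1 residual {residual:.3e})"
        )


# --- evaluation_stats ---------------------------------------------------


class BadPermCount(RWHNError):
    """Permutation count must be at least 1."""


class EmptyCluster(RWHNError):
    """Over-representation analysis received an empty protein set."""


class ItemMismatch(RWHNError):
    """Two rankings to compare do not cover the same item set."""


# --- synthetic_data / pipeline ------------------------------------------


class BadConfig(RWHNError):
    """Inconsistent generator or pipeline configuration."""


class ConfigError(BadConfig):
    """Pipeline configuration is invalid; message names the field."""


class UnknownParameter(RWHNError):
    """A parameter sweep was requested for an unknown parameter name."""
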