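"""Exception hierarchy.

Distinct error states keep loader failures diagnosable: a malformed tree,
a malformed count table and a semantic validation problem raise different
types so callers (and the CLI) can report the failing input precisely.
"""


class FamevolError(Exception):
    """Base class for all package errors."""


class TreeError(FamevolError):
    """Structural problem with a species tree (topology, labels, lengths)."""


class CountTableError(FamevolError):
    """Malformed or inconsistent gene-count table."""


class GeneSetError(FamevolError):
    """Problem building a gene/family set (e.g. nothing mapped)."""


class BranchSetError(FamevolError):
    """A branch set names branches absent from the tree."""


class SimulationError(FamevolError):
    """Synthetic-data generation could not satisfy its contract."""


class FitError(FamevolError):
    """Model fitting failed or the design is degenerate."""
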