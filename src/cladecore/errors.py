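"""Exception hierarchy shared across the package."""


class CladecoreError(Exception):
    """Base class for all package-specific errors."""


class EmptyInputError(CladecoreError):
    """An input file or collection was empty where content is required."""


class AlphabetError(CladecoreError):
    """A sequence contains residues outside its declared alphabet."""


class CoordinateError(CladecoreError):
    """A feature coordinate is inconsistent with its genome."""


class UndefinedValueError(CladecoreError):
    """A statistic is undefined for the given input (e.g. empty range)."""


class DegenerateAxisError(CladecoreError):
    """GC skew carries no usable replication-axis signal."""


class IncompleteGraphError(CladecoreError):
    """An orthology operation requires all pairwise comparisons."""


class InsufficientReplicatesError(CladecoreError):
    """A statistical test requires more replicates than provided."""
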