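"""Exception hierarchy shared across the package."""


class RoseError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RoseError):
    """An input file violates its format contract (FASTA/GFF3/BedGraph/TSV)."""


class ParameterError(RoseError):
    """A parameter value is outside its documented domain."""


class NoSignalError(RoseError):
    """An operation that needs read-start signal received an all-zero profile."""
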