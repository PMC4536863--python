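"""Exception hierarchy.

Everything user-facing raises a subclass of :class:`MsapopError` so the CLI
can distinguish user errors (bad files, bad config) from internal faults.
"""


class MsapopError(Exception):
    """Base class for all errors raised by msapop."""


class BandMatrixFormatError(MsapopError):
    """A band-matrix or metadata file violates the documented dialect."""


class AssayMismatchError(MsapopError):
    """An operation requires a different assay (MSAP vs TMD) than supplied."""


class DegenerateTreeError(MsapopError):
    """A dendrogram operation needs at least two leaves."""


class UndefinedStatisticError(MsapopError):
    """A level/fraction/similarity has an empty denominator."""


class ConfigError(MsapopError):
    """A run or simulation configuration is invalid."""
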