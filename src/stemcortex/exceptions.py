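"""Exception hierarchy shared across the package."""


class StemCortexError(Exception):
    """Base class for all package errors."""


class FormatError(StemCortexError, ValueError):
    """A file or table violates the expected format (duplicate labels,
    non-numeric coordinates, missing columns...)."""


class ShapeError(StemCortexError, ValueError):
    """Array dimensions are inconsistent (non-square matrix, grid mismatch)."""


class ParameterError(StemCortexError, ValueError):
    """An argument is outside its valid domain."""


class ConvergenceError(StemCortexError, RuntimeError):
    """An iterative procedure failed to reach its fixed point."""
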