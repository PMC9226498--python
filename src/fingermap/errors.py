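"""Exception hierarchy shared across the package.

CLI subcommands map these onto exit codes: :class:`DataError` -> 3,
:class:`ConvergenceError` -> 4, anything else propagates.
"""


class FingermapError(Exception):
    """Base class for all package errors."""


class DataError(FingermapError):
    """Malformed, inconsistent, or insufficient input data."""


class ConvergenceError(FingermapError):
    """An iterative fit failed to converge or had no binding signal."""
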