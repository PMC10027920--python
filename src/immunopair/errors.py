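"""Exception hierarchy.

Exit-code mapping used by the CLI: :class:`ParameterError` -> 2, every other
:class:`ImmunopairError` -> 1.
"""


class ImmunopairError(Exception):
    """Base class for all package errors."""


class ParameterError(ImmunopairError):
    """Invalid user-supplied parameter (CLI exit code 2)."""


class DataFormatError(ImmunopairError):
    """Malformed input file (missing column, bad dialect, ...)."""


class DataError(ImmunopairError):
    """Structurally valid input that violates a semantic precondition."""
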