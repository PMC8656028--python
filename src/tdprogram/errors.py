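"""Package-wide exception types.

``DataError`` marks invalid scientific input (exit code 3 at the CLI);
``UsageError`` marks a malformed invocation (exit code 2).
"""


class TDProgramError(Exception):
    """Base class for all errors raised by this package."""


class DataError(TDProgramError, ValueError):
    """Input data violates a documented precondition or invariant."""


class UsageError(TDProgramError, ValueError):
    """Invalid combination of configuration options."""
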