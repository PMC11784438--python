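"""Exception hierarchy.

Validation problems (bad values, malformed annotations) and format problems
(unreadable tables, missing columns) are kept distinct so the CLI can map
them to different exit codes.
"""


class MethylStoichError(Exception):
    """Base class for all package errors."""


class ValidationError(MethylStoichError, ValueError):
    """A value violates a documented invariant (bad residue, bad range, ...)."""


class TableFormatError(MethylStoichError, ValueError):
    """A delimited input table cannot be interpreted under the given dialect."""

    def __init__(self, message: str, row_errors: list[str] | None = None):
        self.row_errors = list(row_errors or [])
        if self.row_errors:
            message = message + "\n" + "\n".join(self.row_errors)
        super().__init__(message)
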