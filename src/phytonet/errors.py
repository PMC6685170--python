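"""Exception hierarchy shared by all pipeline stages.

``InputError`` covers malformed or inconsistent user input (CLI exit code 1);
any other failure is an internal error (exit code 2).
"""


class PhytonetError(Exception):
    """Base class for all package errors."""

    exit_code = 2


class InputError(PhytonetError):
    """Invalid input data or parameters supplied by the caller."""

    exit_code = 1


class SynthSpecError(InputError):
    """Synthetic-data specification is internally inconsistent or unsatisfiable."""
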