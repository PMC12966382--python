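"""Exception hierarchy.

Two broad failure classes map onto the CLI exit-code contract:
``InputError`` (exit 1) for malformed or inconsistent user input, and
``ComputationError`` (exit 2) for failures arising during computation on
valid input (broken geometry, non-finite loss, failed embeddings).
"""


class PhysdualError(Exception):
    """Base class for all package errors."""


class InputError(PhysdualError, ValueError):
    """Invalid, malformed or mutually inconsistent input."""


class ComputationError(PhysdualError, RuntimeError):
    """A computation failed on structurally valid input."""
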