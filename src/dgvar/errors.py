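"""Exception hierarchy.

``InputError`` (bad user input, exit code 1) is distinguished from any other
failure (internal, exit code 2) so the CLI can map them to exit codes.
"""


class DgvarError(Exception):
    """Base class for all package errors."""


class InputError(DgvarError):
    """Malformed or inconsistent user-supplied input."""


class ParseError(InputError):
    """A file could not be parsed; the message names the file and location."""
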