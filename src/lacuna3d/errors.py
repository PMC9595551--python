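"""Exception hierarchy with a stable exit-code contract for the CLI.

0 = success, 2 = configuration error, 3 = I/O error, 4 = numeric or
degenerate-input error.
"""


class LacunaError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(LacunaError):
    """Invalid configuration: bad preset name, nonpositive spacing, ..."""

    exit_code = 2


class InputError(LacunaError):
    """I/O failure: missing file, inconsistent slice shapes, unwritable path."""

    exit_code = 3


class NumericError(LacunaError):
    """Numeric/degenerate-input failure: empty point set, zero volume, ..."""

    exit_code = 4


class PackingError(NumericError):
    """Phantom packing gave up before placing the requested object count."""

    def __init__(self, message, achieved=0, requested=0):
        super().__init__(message)
        self.achieved = achieved
        self.requested = requested
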