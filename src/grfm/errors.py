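"""Exception types shared across the pipeline.

``InputError`` maps to CLI exit code 2, ``NumericalError`` to 3.
"""


class GrfmError(Exception):
    """Base class for package errors."""


class InputError(GrfmError, ValueError):
    """Invalid or inconsistent user-supplied data (schema, units, events)."""


class ConfigurationError(GrfmError, ValueError):
    """Invalid configuration: missing segment lengths, bad filter setup, ..."""


class NumericalError(GrfmError, RuntimeError):
    """A computation could not be carried out (degenerate phase, zero energy)."""
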