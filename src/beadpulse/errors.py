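"""Exception hierarchy shared across the pipeline stages.

The CLI maps these onto distinct exit codes (config 2, data format 3,
numerical failure 4).
"""


class BeadPulseError(Exception):
    """Base class for all package errors."""


class ConfigError(BeadPulseError):
    """Invalid configuration or parameter outside its domain."""


class FormatError(BeadPulseError):
    """Malformed input file (wrong columns, bad time base, NaNs)."""


class NumericalError(BeadPulseError):
    """A fit or decomposition failed (singular matrix, non-convergence)."""
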