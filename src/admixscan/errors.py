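"""Exception hierarchy shared across the package.

Each class carries the process exit code the CLI maps it to.
"""


class AdmixScanError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(AdmixScanError):
    """Invalid configuration or parameters."""

    exit_code = 2


class DataError(AdmixScanError):
    """Invalid, inconsistent or insufficient input data."""

    exit_code = 3


class NumericalError(AdmixScanError):
    """A numerical procedure failed or is undefined (e.g. zero null scale)."""

    exit_code = 4
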