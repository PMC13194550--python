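"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: InputError -> 1, ConfigurationError -> 2.
"""


class MRTaxaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MRTaxaError):
    """Invalid configuration: bad thresholds, missing columns, bad scenario."""


class InputError(MRTaxaError):
    """Input data unusable: zero valid rows, wrong trait type, etc."""


class HarmonizationError(MRTaxaError):
    """No variant survived harmonization; carries per-category drop counts."""

    def __init__(self, message: str, drop_counts: dict | None = None):
        super().__init__(message)
        self.drop_counts = dict(drop_counts or {})


class EmptyInstrumentError(InputError):
    """Instrument selection left zero variants."""


class InsufficientInstrumentsError(InputError):
    """An estimator was handed fewer variants than its minimum."""


class EstimationError(MRTaxaError):
    """Iterative estimation failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate
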