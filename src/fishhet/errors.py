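"""Exception hierarchy shared across the package."""


class FishhetError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(FishhetError):
    """A required column is missing or a column mapping is invalid."""


class ParseError(FishhetError):
    """A cell value could not be parsed; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class ConfigError(FishhetError):
    """Invalid simulation or pipeline configuration."""


class UndefinedRatioError(FishhetError):
    """Per-cell HER2/CEP17 ratio requested for a nucleus with zero CEP17 signals."""


class InsufficientDataError(FishhetError):
    """Too few nuclei/points/values for the requested statistic."""


class DegenerateSampleError(FishhetError):
    """Zero-variance sample where a mixture fit is undefined."""


class CoordinateError(FishhetError):
    """Spatial operation requested on nuclei without coordinates."""


class PairingError(FishhetError):
    """Paired comparison with mismatched case sets; lists unmatched ids."""

    def __init__(self, message: str, unmatched: list[str] | None = None):
        super().__init__(message)
        self.unmatched = unmatched or []


class SingularFitError(FishhetError):
    """Regression or factor model cannot be fitted (zero variance / singular matrix)."""
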