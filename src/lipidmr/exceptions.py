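"""Exception hierarchy shared across the package.

All errors derive from :class:`LipidMrError` so callers can catch the
package's failures with a single except clause while still distinguishing
bad data from bad configuration.
"""


class LipidMrError(Exception):
    """Base class for all package errors."""


class DomainError(LipidMrError, ValueError):
    """An input value is outside the scientifically meaningful domain
    (negative concentration, zero instrument variance, ...)."""


class ConfigError(LipidMrError, ValueError):
    """A configuration parameter is invalid (unknown analyte, nonpositive
    ceiling, degenerate MAF range, ...)."""


class DataError(LipidMrError, ValueError):
    """Input data violate a structural contract (non-symmetric LD matrix,
    column/model mismatch, empty input, ...)."""


class CollinearityError(DataError):
    """A regression design matrix is rank deficient."""

    def __init__(self, columns=None, message=None):
        self.columns = list(columns) if columns is not None else []
        if message is None:
            message = "rank-deficient design"
            if self.columns:
                message += f"; offending columns: {self.columns}"
        super().__init__(message)


class IdentificationError(DataError):
    """Instruments do not identify the endogenous regressors."""


class DegenerateInstrumentError(DataError):
    """An instrument/score has zero variance or the instrument panel is
    too small for the requested method."""
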