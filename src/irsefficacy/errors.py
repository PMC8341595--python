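"""Exception hierarchy for campaign validation and analysis."""


class IRSEfficacyError(Exception):
    """Base class for all package errors."""


class ConfigurationError(IRSEfficacyError):
    """Bad configuration: missing columns, malformed schema map, invalid settings."""


class ValidationError(IRSEfficacyError):
    """A record or row violates a data invariant."""


class CampaignValidationError(ValidationError):
    """One or more rows of a campaign file failed validation.

    Carries per-row diagnostics so bad rows are reported, never silently dropped.
    """

    def __init__(self, row_errors):
        self.row_errors = list(row_errors)
        lines = "\n".join(f"  row {row}: {msg}" for row, msg in self.row_errors)
        super().__init__(
            f"{len(self.row_errors)} invalid row(s) in campaign file:\n{lines}"
        )


class GatingError(IRSEfficacyError):
    """No matched control data available to gate an exposed arm-month."""


class EmptySeriesError(IRSEfficacyError):
    """An operation received an empty mortality series or empty arm."""


class FitError(IRSEfficacyError):
    """Model fitting failed (non-identifiable design, undefined correction, ...)."""
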