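"""Exception types raised across the pipeline stages."""


class CKDCRAError(Exception):
    """Base class for all package errors."""


class ConfigError(CKDCRAError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class DomainError(CKDCRAError, ValueError):
    """An input outside the domain of an operation (e.g. age < 18)."""


class EmptyStratumError(CKDCRAError, ValueError):
    """A census stratum with positive weight has no survey observations.

    Standardization refuses to silently renormalize; the message lists the
    empty strata so the failure is visible.
    """

    def __init__(self, strata, factor=None, wave=None):
        self.strata = list(strata)
        detail = f" for factor {factor!r} at wave {wave}" if factor else ""
        super().__init__(
            f"no observations{detail} in census strata with positive weight: "
            + ", ".join(map(str, self.strata))
        )


class CollinearityError(CKDCRAError, ValueError):
    """A regression design matrix is rank deficient; names suspect columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(self.columns)
        )


class TrendError(CKDCRAError, ValueError):
    """Not enough waves (or data) to estimate a linear trend."""


class ProjectionError(CKDCRAError, ValueError):
    """No eligible individuals to fit a stratum trend; names the stratum."""
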