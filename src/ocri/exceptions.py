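"""Exception hierarchy shared across the package."""


class OcriError(Exception):
    """Base class for all package-specific errors."""


class FormatError(OcriError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(OcriError, ValueError):
    """Input data violate a documented contract (bad DI, bad label, ...)."""


class SmallSampleError(OcriError):
    """Too few DI values for kernel density estimation (< 10 cells)."""


class UnanalyzableCaseError(OcriError):
    """No diploid population could be identified for a case."""

    def __init__(self, case_id: str, reason: str):
        self.case_id = case_id
        self.reason = reason
        super().__init__(f"case {case_id!r} is unanalyzable: {reason}")


class EmptyCohortError(OcriError, ValueError):
    """A cohort simulation was requested with zero cases."""


class ModelFormatError(OcriError):
    """A model archive is truncated or not a model archive at all."""


class ModelVersionError(OcriError):
    """A model archive was written by an incompatible format version."""
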