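"""Exception hierarchy.

Every loader and estimator raises a subclass of :class:`CausalFCError` so
callers can catch package failures without masking programming errors.
"""


class CausalFCError(Exception):
    """Base class for all package-specific errors."""


class DataFormatError(CausalFCError):
    """Malformed input file (missing header, ragged rows, bad cells...)."""


class DegenerateDataError(CausalFCError):
    """Data too degenerate for a statistic (zero variance, singular cov)."""


class StabilityError(CausalFCError):
    """A simulated process is (or became) numerically unstable."""


class OrientationError(CausalFCError):
    """Edge orientation produced a directed cycle."""


class CollinearityError(CausalFCError):
    """Regressor matrix is rank deficient."""
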