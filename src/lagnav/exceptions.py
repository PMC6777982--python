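"""Exception hierarchy.

Invalid arguments raise the built-in :class:`ValueError`; the classes here
mark conditions that are data-dependent rather than caller mistakes.
"""


class LagnavError(Exception):
    """Base class for package-specific errors."""


class DegenerateSignalError(LagnavError):
    """A signal (or correlogram) carries no usable variance.

    Raised for constant time series, flat cross-correlograms and
    zero-variance samples in statistical tests.
    """


class CollinearityError(LagnavError):
    """A regression design matrix is rank deficient."""


class SchemaError(LagnavError):
    """An on-disk cohort or matrix file does not match the expected schema."""
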