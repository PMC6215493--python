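"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: DataMismatchError -> 3 (data error),
RankDeficiencyError / NumericalError -> 4 (numerical failure), anything
click raises itself -> 2 (user error).
"""


class GsvdcnaError(Exception):
    """Base class for all package errors."""


class DataMismatchError(GsvdcnaError, ValueError):
    """Inconsistent dimensions, identifiers, or coordinates between inputs."""


class RankDeficiencyError(GsvdcnaError, ValueError):
    """A profile matrix is numerically rank deficient (GSVD precondition)."""


class NumericalError(GsvdcnaError, RuntimeError):
    """A numerical routine failed to converge or produced unusable output."""
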