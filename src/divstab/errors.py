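"""Exception hierarchy shared across the package.

Every error raised on bad user input derives from :class:`DivstabError`
so callers can catch one type at the pipeline boundary.
"""


class DivstabError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(DivstabError, ValueError):
    """An argument violates a documented precondition."""


class MissingDataError(DivstabError):
    """Required observations are absent (e.g. no daily records for a site-year)."""


class DegenerateWindowError(DivstabError):
    """Too few years inside a sampling window to form a summary."""


class DegenerateStabilityError(DivstabError):
    """Community total has zero temporal variance; stability is undefined."""


class DegenerateTraitsError(DivstabError):
    """Encoded trait matrix has no variance; no principal axis exists."""


class CollinearityError(DivstabError):
    """Design matrix is rank deficient; names the aliased columns."""

    def __init__(self, aliased: list[str]):
        self.aliased = list(aliased)
        super().__init__(f"rank-deficient design; aliased columns: {', '.join(self.aliased)}")


class CycleError(DivstabError):
    """A directed cycle where a DAG is required; names the cycle."""


class ModelSpecError(DivstabError):
    """Malformed model-DSL text (bad line, correlated error between adjacent vertices...)."""


class UndefinedStatisticError(DivstabError):
    """A statistic is undefined for the given input (constant vector, n <= K+1...)."""
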