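"""Exception hierarchy for redikit.

Every precondition violation named in the public API raises a distinct
subclass of :class:`RedikitError` so callers can handle them individually.
"""


class RedikitError(Exception):
    """Base class for all redikit errors."""


class MissingIndexError(RedikitError):
    """A BAM or FASTA file lacks its companion index."""


class UnsortedBamError(RedikitError):
    """The BAM header does not declare coordinate sorting."""


class UnknownContigError(RedikitError):
    """A requested chromosome is absent from the file header."""


class IntervalBoundsError(RedikitError):
    """An interval is empty or falls outside its chromosome."""


class PositionOutsideReadError(RedikitError):
    """A genomic position does not intersect the read's reference span."""


class ZeroCoverageError(RedikitError):
    """Substitution frequencies requested for an empty pileup column."""


class InvalidReferenceBaseError(RedikitError):
    """Reference symbol outside {A, C, G, T, N}."""


class UnsortedRecordsError(RedikitError):
    """Output records are not in (region, position) order."""


class MissingTemporaryError(RedikitError):
    """One or more per-interval temporary files are missing at merge time.

    The missing paths are listed in ``args[0]``.
    """


class WorkerFailureError(RedikitError):
    """A worker failed while processing an interval; names the interval."""


class DegenerateFitError(RedikitError):
    """Time-model fit attempted on degenerate observations."""


class InsufficientSitesError(RedikitError):
    """Not enough eligible positions to plant the requested sites."""
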