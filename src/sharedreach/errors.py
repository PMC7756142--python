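"""Exception hierarchy shared across the pipeline.

Each stage raises a specific subclass so the CLI can map failures to
stable exit codes (parse 2, incomplete design 3, no data 4).
"""


class SharedReachError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(SharedReachError, ValueError):
    """An argument violates a documented precondition."""


class AlignmentError(SharedReachError):
    """Two trajectories have no usable common time support."""


class NoTouchError(SharedReachError):
    """The hand never enters the target cube before the recording ends."""


class DegenerateSampleError(SharedReachError):
    """A statistic is undefined for the sample (constant data, all-zero differences...)."""


class IncompleteDesignError(SharedReachError):
    """A repeated-measures table is missing cells."""


class ParseError(SharedReachError):
    """An input file violates the trajectory/ratings CSV dialect."""


class NoDataError(SharedReachError):
    """An operation received an empty table."""
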