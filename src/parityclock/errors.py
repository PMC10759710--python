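"""Exception hierarchy.

Contract violations (bad shapes, invalid parameter ranges) raise
:class:`ContractError`; malformed input files raise :class:`ParseError`;
numerical failures inside solvers raise :class:`ConvergenceError`; and
statistically impossible estimation requests (e.g. all-zero count vectors)
raise :class:`EstimationError`.  All inherit from :class:`ParityClockError`
so callers can catch the package's failures with a single clause.
"""


class ParityClockError(Exception):
    """Base class for all errors raised by parityclock."""


class ContractError(ParityClockError, ValueError):
    """An argument violates a documented precondition."""


class ParseError(ParityClockError, ValueError):
    """An input file does not conform to the expected dialect."""


class ConvergenceError(ParityClockError, RuntimeError):
    """A numerical solver failed to bracket or converge."""


class EstimationError(ParityClockError, RuntimeError):
    """The requested estimate is undefined for the given data."""
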