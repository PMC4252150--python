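"""Exception hierarchy shared across the package.

Readers raise :class:`FormatError` for malformed files and :class:`DataError`
for well-formed files carrying invalid values; analysis code raises
:class:`ParameterError` for bad arguments and :class:`ConsistencyError` when
two otherwise-valid objects disagree (e.g. a block schedule longer than its
trace). The CLI maps these onto exit codes (2 validation, 3 data).
"""


class SwayError(Exception):
    """Base class for all errors raised by swayrqa."""


class FormatError(SwayError):
    """A file does not conform to the documented dialect/schema."""


class DataError(SwayError):
    """Values are out of range, missing, or otherwise unusable."""


class ParameterError(SwayError):
    """An argument violates its documented constraints."""


class ConsistencyError(SwayError):
    """Two valid objects are mutually inconsistent."""


class ScheduleError(ConsistencyError):
    """A block schedule cannot be applied to a trace."""


class DegenerateGeometryError(DataError):
    """Point cloud too degenerate for an ellipse fit (collinear/constant)."""


class DegenerateDataError(DataError):
    """A statistic is undefined for this input (e.g. zero variance)."""


class PairSpecError(ParameterError):
    """A correlation pair references an unknown feature/outcome column."""
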