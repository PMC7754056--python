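"""Exception hierarchy.

Grouped by how the command-line layer maps them to exit codes:
data/format problems (exit 3) versus statistical preconditions (exit 4).
"""


class GendulfError(Exception):
    """Base class for all errors raised by this package."""


class DataError(GendulfError):
    """A problem with input data or its format (CLI exit code 3)."""


class FormatError(DataError):
    """Malformed file: bad header, ragged rows, dimension mismatch."""


class DuplicateIdentifierError(DataError):
    """Duplicate gene or sample identifier where uniqueness is required."""


class ValueRangeError(DataError):
    """Negative, non-finite, or non-numeric value where an abundance is expected."""


class LabelError(DataError):
    """Inconsistent case/control labelling of a sample."""


class CompositionError(DataError):
    """A case-control study with an empty arm."""


class MissingGeneError(DataError):
    """A required gene identifier is absent from the matrix."""


class StatisticalPreconditionError(GendulfError):
    """A statistical requirement of a test is violated (CLI exit code 4)."""


class EligibilityError(StatisticalPreconditionError):
    """Gene fails the low-expression eligibility screen (constant or zero-heavy)."""


class SampleSizeError(StatisticalPreconditionError):
    """A stratum or cohort is too small for the requested resampling."""


class DomainError(StatisticalPreconditionError):
    """Test parameters outside their mathematical domain."""


class DegeneratePartitionError(StatisticalPreconditionError):
    """Isoform ratio split leaves the high or low group empty."""


class SpecificationError(GendulfError):
    """Invalid or inconsistent simulation specification."""
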