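"""Exception hierarchy shared by all pipeline stages."""


class IsocoupleError(Exception):
    """Base class for all isocouple errors."""


class ParseError(IsocoupleError):
    """A malformed input file (GTF, SJ.out.tab, BED)."""


class EmptyDatabaseError(IsocoupleError):
    """No usable records remain after filtering."""


class DataError(IsocoupleError):
    """Inconsistent data within a single input (e.g. mixed-strand transcript)."""


class ConsistencyError(IsocoupleError):
    """Two inputs that must come from the same run do not match."""


class UsageError(IsocoupleError):
    """A parameter combination that can never be valid."""


class DegenerateTableError(IsocoupleError):
    """A contingency table on which the requested statistic is undefined."""


class MissingIndexError(IsocoupleError):
    """A coordinate-sorted BAM is not indexed."""


class LayoutError(IsocoupleError):
    """A simulation configuration that cannot be laid out on the contig."""
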