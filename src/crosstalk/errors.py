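"""Exception hierarchy for the crosstalk pipeline.

Every stage raises a subclass of :class:`CrosstalkError`, so callers (and the
pipeline driver) can distinguish malformed input from infeasible parameters
and from internal inconsistencies.
"""


class CrosstalkError(Exception):
    """Base class for all package errors."""


class FormatError(CrosstalkError):
    """Malformed external input (TSV/GMT/metadata); message names the offending
    file location (line, row/column, duplicated identifier)."""


class ParameterError(CrosstalkError):
    """Infeasible or out-of-range parameters (counts, fractions, thresholds)."""


class ConsistencyError(CrosstalkError):
    """Internally inconsistent objects passed between stages, e.g. a
    ligand/receptor classification referencing symbols absent from the pair
    table it was supposedly derived from."""
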