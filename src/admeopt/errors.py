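"""Exception types shared across the package."""


class AdmeoptError(Exception):
    """Base class for all package errors."""


class SchemaError(AdmeoptError):
    """A required column is absent or an input table is malformed."""


class ParseError(AdmeoptError):
    """A cell could not be parsed; carries row/column context."""

    def __init__(self, message: str, row=None, column=None):
        super().__init__(message)
        self.row = row
        self.column = column


class ValidationError(AdmeoptError):
    """A value violates a domain invariant (duplicate id, bad range...)."""


class DegenerateInputError(AdmeoptError):
    """Input too degenerate to operate on (e.g. <2 distinct scores)."""


class UndefinedMetricError(AdmeoptError):
    """A metric's denominator is empty; distinct from the value 0."""


class ThresholdUnavailableError(AdmeoptError):
    """No conventional threshold exists for this algorithm (PhyloP, PhastCons)."""
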