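"""Exception types shared across the pipeline."""


class NuclinkerError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NuclinkerError):
    """A file does not conform to the expected layout (missing columns, empty, ...)."""


class RecordError(NuclinkerError):
    """A single record is invalid; the message names the offending row."""


class CoordinateError(NuclinkerError):
    """An interval does not fit on its chromosome."""


class ParseError(NuclinkerError):
    """A cell could not be parsed; the message names the line."""


class LabelError(NuclinkerError):
    """A class label is outside the {1, 2} coding."""


class ConstantFeatureError(NuclinkerError):
    """A statistic is undefined because the feature has zero variance."""
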