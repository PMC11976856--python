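"""Exception hierarchy shared across pipeline stages."""


class NanopotencyError(Exception):
    """Base class for all pipeline errors."""


class DesignError(NanopotencyError):
    """Invalid experimental design (missing dose 0, single-level factor, ...)."""


class NormalizationError(NanopotencyError):
    """Fold-effect normalization could not be carried out."""


class FitError(NanopotencyError):
    """Not enough usable data to fit the potency model."""


class GenerationError(NanopotencyError):
    """A synthetic-data generator could not satisfy its contract."""


class GMTParseError(NanopotencyError):
    """Malformed gene-set (GMT) input; carries the offending line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number
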