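"""Exception hierarchy for epivector."""


class EpivectorError(Exception):
    """Base class for all epivector errors."""


class ConfigurationError(EpivectorError):
    """Inconsistent or invalid configuration (layouts, simulation settings)."""


class AnnotationError(EpivectorError):
    """Vector annotation is missing required features (e.g. an ITR)."""


class ValidationError(EpivectorError):
    """A dataset violates a precondition (missing Tn5 match, mixed modes...)."""


class ParseError(EpivectorError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path: str | None = None,
                 line_number: int | None = None):
        self.path = path
        self.line_number = line_number
        prefix = ""
        if path is not None:
            prefix += f"{path}"
        if line_number is not None:
            prefix += f":{line_number}"
        super().__init__(f"{prefix}: {message}" if prefix else message)
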