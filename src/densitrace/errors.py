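"""Exception hierarchy."""


class DensitraceError(Exception):
    """Base class for all densitrace errors."""


class ConfigError(DensitraceError):
    """A size/score configuration file is malformed or violates an invariant."""


class TraceValidationError(DensitraceError):
    """A density-trace file or object violates the trace schema.

    ``where`` pinpoints the offending element as (trace index/id,
    segment index, element index) when available.
    """

    def __init__(self, message: str, where: tuple | None = None):
        self.where = where
        if where is not None:
            message = f"{message} (at {where})"
        super().__init__(message)
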