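"""Exception hierarchy shared across the package."""


class ThermolncError(Exception):
    """Base class for all package-specific failures."""


class FormatError(ThermolncError):
    """A file violated the expected dialect or an invariant of its contents.

    Carries the offending path and (1-based) line number when known.
    """

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)


class ValidationError(ThermolncError):
    """An in-memory object violated a declared invariant."""


class SimulationError(ThermolncError):
    """Synthetic-data generation could not satisfy its placement constraints."""


class PipelineError(ThermolncError):
    """A pipeline stage failed; the message names the stage."""
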