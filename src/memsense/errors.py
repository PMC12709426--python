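"""Exception hierarchy for the memsense pipeline.

Every failure mode named in the module contracts maps onto one of these, so
callers (and the CLI) can distinguish bad files from bad science.
"""


class MemsenseError(Exception):
    """Base class for all pipeline errors."""


class FormatError(MemsenseError):
    """A coordinate or table file does not conform to its declared format."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class StructuralError(MemsenseError):
    """Inputs are individually valid but mutually inconsistent (e.g. atom-count
    mismatch between topology and trajectory, lipid missing required beads)."""


class ParameterError(MemsenseError):
    """A generator or analysis parameter is outside its valid domain."""


class InputError(MemsenseError):
    """An analysis received empty or otherwise unusable input data."""


class AnalysisError(MemsenseError):
    """A computation could not produce a result (all frames invalid,
    insufficient data, degenerate fit)."""


class StateDetectionError(AnalysisError):
    """A free-energy profile has no local minimum inside a required state
    window (e.g. monotonic profile with no transmembrane minimum)."""


class FitError(AnalysisError):
    """Surface fit is underdetermined or rank-deficient."""
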