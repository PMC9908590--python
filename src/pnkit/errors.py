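"""Exception hierarchy.

Every error carries a stable machine-readable ``code`` so CLI consumers and
tests can dispatch on it without parsing messages.
"""


class PnkitError(Exception):
    """Base class for all toolkit errors."""

    code = "PNKIT_ERROR"

    def __init__(self, message: str, **context):
        super().__init__(message)
        self.context = context


# --- document / format errors -------------------------------------------------

class ParseError(PnkitError):
    """A file could not be parsed into the expected structure."""

    code = "PARSE_ERROR"


class VersionError(ParseError):
    code = "VERSION_ERROR"


class StructureError(PnkitError):
    """A parsed structure violates terminology-tree constraints."""

    code = "STRUCTURE_ERROR"


class EmptyTerminologyError(StructureError):
    code = "EMPTY_TERMINOLOGY"


class GeometryError(PnkitError):
    code = "GEOMETRY_ERROR"


class TimeOrderError(ParseError):
    code = "TIME_ORDER_ERROR"


class EventTypeError(ParseError):
    code = "TYPE_ERROR"


class UnknownTermError(PnkitError):
    code = "UNKNOWN_TERM"


class AmbiguousBundleError(PnkitError):
    code = "AMBIGUOUS_BUNDLE"


class EmptyCohortError(PnkitError):
    code = "EMPTY_COHORT"


# --- image / pipeline errors --------------------------------------------------

class DegenerateHistogramError(PnkitError):
    code = "DEGENERATE_HISTOGRAM"


class InsufficientTissueError(PnkitError):
    code = "INSUFFICIENT_TISSUE"


class DegenerateStainsError(PnkitError):
    code = "DEGENERATE_STAINS"


class InsufficientPatchesError(PnkitError):
    code = "INSUFFICIENT_PATCHES"


class EmptyTraceError(PnkitError):
    code = "EMPTY_TRACE"


class InputContractError(PnkitError):
    code = "INPUT_CONTRACT"


class ConfigError(PnkitError):
    code = "CONFIG_ERROR"
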