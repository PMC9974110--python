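"""Exception hierarchy for the icdetect pipeline."""


class IcdetectError(Exception):
    """Base class for all icdetect errors."""


class ParameterError(IcdetectError, ValueError):
    """An out-of-range or inconsistent parameter value."""


class GeometryError(IcdetectError, ValueError):
    """Invalid or out-of-bounds geometry."""


class FormatError(IcdetectError, ValueError):
    """Unreadable or malformed file content."""


class IntegrityError(IcdetectError, ValueError):
    """Inconsistent records (duplicates, cross-slide mixups)."""


class BoundsError(IcdetectError, ValueError):
    """A coordinate outside the slide."""


class DataError(IcdetectError, ValueError):
    """Degenerate data (single-class sets, length mismatches)."""


class ConfigError(IcdetectError, ValueError):
    """Unsupported or inconsistent configuration."""


class StateError(IcdetectError, RuntimeError):
    """An operation invoked before its prerequisites exist."""


class ContractError(IcdetectError, ValueError):
    """A call that violates an inter-module contract."""


class SplitError(IcdetectError, ValueError):
    """A dataset split that cannot be formed."""


class NoEpitheliumError(IcdetectError, RuntimeError):
    """A slide on which no epithelial patch survives filtering.

    Deliberately distinct from a numeric score of zero: a slide without
    scoreable epithelium is neither an IC nor a Rest call.
    """
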