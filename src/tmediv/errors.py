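"""Exception hierarchy.

All package-raised errors derive from :class:`TmedivError` so callers (and the
CLI) can distinguish data problems from configuration problems.
"""


class TmedivError(Exception):
    """Base class for all package errors."""


class FormatError(TmedivError, ValueError):
    """An input file does not conform to the expected dialect."""


class ValidationError(TmedivError, ValueError):
    """Input values violate a documented precondition."""


class StateError(TmedivError, RuntimeError):
    """An operation was called before its prerequisites (e.g. scoring)."""


class GeometryError(TmedivError, ValueError):
    """An annotation polygon is invalid (e.g. self-intersecting)."""


class FitError(TmedivError, RuntimeError):
    """A statistical model could not be fitted (no events, degenerate design)."""


class ConfigError(TmedivError, ValueError):
    """A run configuration is invalid."""
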