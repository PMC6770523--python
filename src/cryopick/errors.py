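"""Exception hierarchy.

All user-facing failures derive from :class:`CryopickError` so the CLI can
distinguish "you asked for something impossible" (exit 1) from genuine bugs
(exit 2).
"""


class CryopickError(Exception):
    """Base class for all expected, user-facing errors."""


class FormatError(CryopickError):
    """An input file exists but is not in an accepted format."""


class ParameterError(CryopickError):
    """A configuration value is out of its legal range or inconsistent."""


class DegenerateInputError(CryopickError):
    """The input is valid but carries no usable signal (e.g. a flat image)."""


class PlacementError(CryopickError):
    """Synthetic particle placement failed under the separation constraint."""
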