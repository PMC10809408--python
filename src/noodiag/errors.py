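"""Exception hierarchy.

Everything raised on purpose by this package derives from :class:`NoodiagError`
so callers (and the CLI) can distinguish domain failures from bugs.
"""


class NoodiagError(Exception):
    """Base class for all errors raised by noodiag."""


class InvalidOccupancyError(NoodiagError, ValueError):
    """An occupation number lies outside the physically allowed range."""


class NormalizationError(NoodiagError, ValueError):
    """A size-intensive quantity was requested for zero electrons."""


class DimensionError(NoodiagError, ValueError):
    """Array dimensions are inconsistent with the electron counts."""


class MissingThresholdError(NoodiagError, KeyError):
    """No diagnostic thresholds are registered for the requested method."""


class SymmetryError(NoodiagError, ValueError):
    """A matrix that must be (Hermitian-)symmetric is not."""


class DegenerateInputError(NoodiagError, ValueError):
    """An input with no information content (e.g. an all-zero CI vector)."""


class FormatError(NoodiagError, ValueError):
    """A file could not be parsed in the declared or sniffed format."""


class ModelSpecError(NoodiagError, ValueError):
    """A model-system specification is invalid or exceeds the size guard."""
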