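"""Exception hierarchy shared by every spatnet module.

All domain errors derive from :class:`SpatnetError` so callers can catch a
single base class; the three subclasses distinguish contract violations
(:class:`ValidationError`), mismatched image/mask geometry
(:class:`DimensionError`) and mathematically degenerate inputs such as a
constant channel (:class:`DegenerateInputError`).
"""


class SpatnetError(Exception):
    """Base class for all spatnet domain errors."""


class ValidationError(SpatnetError, ValueError):
    """An argument violates a documented precondition or invariant."""


class DimensionError(ValidationError):
    """Two arrays that must share a shape do not."""


class DegenerateInputError(SpatnetError, ValueError):
    """The input is degenerate for the requested operation (e.g. constant)."""
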