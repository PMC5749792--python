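"""Exception hierarchy.

Everything derives from :class:`GeoregError` (a ``ValueError``) so callers can
catch the package's failures with one clause while standard library semantics
are preserved.
"""


class GeoregError(ValueError):
    """Base class for all georeg errors."""


class DimensionError(GeoregError):
    """Image too small for the requested operation."""


class ParameterError(GeoregError):
    """A parameter is outside its valid range."""


class BorderError(GeoregError):
    """A patch or sampling window does not fit inside the image."""


class DescriptorError(GeoregError):
    """Descriptor malformed (wrong length) or sets incompatible."""


class InsufficientPointsError(GeoregError):
    """Fewer points than the operation requires."""


class DegenerateGeometryError(GeoregError):
    """Coincident or otherwise degenerate point configurations."""


class InsufficientMatchesError(GeoregError):
    """Fewer matches than the consensus sampler needs."""


class CoverageError(GeoregError):
    """A synthetic warp pushed all content out of frame."""
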