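"""Exception hierarchy for the screening pipeline.

``run_screen`` converts per-site :class:`SiteError` subclasses into excluded
candidates instead of aborting; everything else propagates.
"""


class OmescanError(Exception):
    """Base class for all package errors."""


class FormatError(OmescanError):
    """Unreadable, unrecognized, or malformed input file."""


class SiteError(OmescanError):
    """A failure confined to a single candidate site."""


class MissingAtomError(SiteError):
    """A required parent atom is absent from the residue."""


class GeometryError(SiteError):
    """Degenerate reference geometry (e.g. collinear frame atoms)."""


class OutsideMapError(SiteError):
    """A probe position fell outside the interpolable map domain."""
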