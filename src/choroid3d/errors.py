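"""Exception hierarchy for the choroid3d pipeline."""


class Choroid3DError(Exception):
    """Base class for all choroid3d errors."""


class ValidationError(Choroid3DError):
    """A parameter or input failed validation before any computation ran."""


class GeometryError(Choroid3DError):
    """A geometric constraint was violated (e.g. a vessel leaves the slab)."""


class FormatError(Choroid3DError):
    """An input file or directory does not match the expected format."""


class IntegrityError(Choroid3DError):
    """Internally inconsistent data (e.g. crossing boundary surfaces)."""
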