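"""Exception hierarchy used across the package."""


class ChalkcamError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ChalkcamError, ValueError):
    """An input violates a documented pre-condition or invariant."""


class ConfigurationError(ChalkcamError, ValueError):
    """An unknown backbone, layer name or option was requested."""


class DataError(ChalkcamError, ValueError):
    """A dataset is unusable (e.g. a single-class training split)."""


class CapacityError(ChalkcamError, RuntimeError):
    """A plate layout cannot fit the requested grains without overlap."""


class EmptyMaskError(ChalkcamError, ValueError):
    """Grain-foreground segmentation found no foreground pixels."""


class ParseError(ChalkcamError, ValueError):
    """An annotation file could not be parsed."""
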