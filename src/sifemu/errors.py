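"""Exception hierarchy.

Everything raised on purpose derives from :class:`SifemuError` so callers
(and the CLI) can distinguish domain errors from genuine bugs.
"""


class SifemuError(Exception):
    """Base class for all errors raised by sifemu."""


class FormatError(SifemuError, ValueError):
    """A file does not follow the expected on-disk format."""


class ConsistencyError(SifemuError, ValueError):
    """Internally inconsistent data (e.g. band count vs. wavelength list)."""


class UnsupportedDialectError(FormatError):
    """The file is recognisable but uses an unsupported variant."""


class ArgumentError(SifemuError, ValueError):
    """An argument violates a precondition."""


class ShapeError(SifemuError, ValueError):
    """Array shapes or band grids do not match."""


class IntegrityError(SifemuError):
    """A stored artifact is truncated or corrupted."""


class UnsupportedVersionError(SifemuError):
    """A stored artifact declares a format version this build cannot read."""


class NumericalError(SifemuError):
    """A numerical procedure failed beyond what regularization can absorb."""
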