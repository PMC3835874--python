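"""Exception types raised across the package."""


class BlockNLMError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BlockNLMError, ValueError):
    """An argument violates a documented precondition."""


class DimensionParseError(BlockNLMError, ValueError):
    """A filename carries no parsable ``<W>x<H>x<F>`` dimension token."""


class SizeMismatchError(BlockNLMError, ValueError):
    """A raw file's byte count is inconsistent with the stated dimensions."""


class VolumeFormatError(BlockNLMError, ValueError):
    """An unsupported or unreadable volume file format."""
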