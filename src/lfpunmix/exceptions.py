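"""Exception hierarchy shared by all stages."""


class LfpUnmixError(Exception):
    """Base class for errors raised by this package."""


class FormatError(LfpUnmixError, ValueError):
    """A file does not conform to the expected on-disk layout."""


class ValidationError(LfpUnmixError, ValueError):
    """In-memory data violates a documented invariant."""
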