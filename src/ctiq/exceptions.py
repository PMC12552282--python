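"""Package-specific error types.

All inherit :class:`CtiqError` (itself a ``ValueError``) so callers can catch
either the specific condition or anything raised by this package.
"""


class CtiqError(ValueError):
    """Base class for all errors raised by ctiq."""


class EmptyRoiError(CtiqError):
    """An ROI or tissue mask contains no valid pixels."""


class RoiTooSmallError(CtiqError):
    """The ROI cannot host the requested filter window or candidate circles."""


class BimodalityError(CtiqError):
    """A two-tissue split was requested on an ROI without a bimodal histogram."""


class ZeroNoiseError(CtiqError):
    """The minimum-noise estimate is zero, so SNR/CNR are undefined."""


class InsufficientBoundaryError(CtiqError):
    """The tissue interface is too short to measure edge sharpness."""


class InputFormatError(CtiqError):
    """A file or ROI specification could not be parsed."""
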