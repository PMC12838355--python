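"""Exception and warning types shared across the package."""


class ValidationError(ValueError):
    """A parameter or input violates a documented invariant."""


class DimensionError(ValueError):
    """Array shapes or physical dimensions are inconsistent."""


class ChannelNotFoundError(KeyError):
    """A requested channel name is not present in the stack."""


class SegmentationWarning(UserWarning):
    """Non-fatal segmentation degeneracy (empty foreground, single-class Otsu)."""


class QuantificationWarning(UserWarning):
    """Non-fatal quantification issue (low pixel count, truncated histogram)."""
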