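"""Exception types shared across the package."""


class PCGError(Exception):
    """Base class for pcgfusion errors."""


class DegenerateSignalError(PCGError):
    """Raised for constant, empty, or otherwise unusable input signals."""


class SegmentationError(PCGError):
    """Raised when no plausible S1/S2 structure can be located."""


class SelectionError(PCGError):
    """Raised when an IMF selection rule cannot be applied."""
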