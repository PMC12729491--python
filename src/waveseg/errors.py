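"""Exception hierarchy for input and configuration contract violations."""


class WavesegError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(WavesegError):
    """Invalid data crossing a public operation boundary (NaN, non-binary mask, ...)."""


class ConfigurationError(WavesegError):
    """Inconsistent or out-of-contract configuration (channel mismatch, bad stages)."""


class FusionShapeError(WavesegError):
    """The two streams handed to the fusion block disagree in shape."""


class CapacityError(WavesegError):
    """Token count exceeds the exact-attention budget; place the block deeper."""


class GenerationError(WavesegError):
    """The synthetic-data generator could not satisfy its output invariants."""
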