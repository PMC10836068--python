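"""Exception types shared across the pipeline stages."""


class FlimetabError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(FlimetabError, ValueError):
    """An acquisition or pipeline configuration violates an invariant."""


class PartitionError(FlimetabError, ValueError):
    """Scene regions overlap or fail to cover the frame."""


class EmptySelectionError(FlimetabError, RuntimeError):
    """A mask or filter selected no pixels/values."""


class DegenerateSampleError(FlimetabError, ValueError):
    """A value sample has zero variance and cannot support a Gaussian fit."""
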