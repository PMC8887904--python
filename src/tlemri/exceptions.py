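"""Package-wide error types. All derive from ValueError so callers can catch broadly."""


class SizingError(ValueError):
    """Image dimensions too small to place the anatomical ROIs."""


class ConfigurationError(ValueError):
    """Inconsistent cohort / run configuration."""


class ShapeError(ValueError):
    """Array shape mismatch between operands."""


class PoolSizeError(ValueError):
    """Neighbour pool or minority class too small for the requested k."""


class ClassBalanceError(ValueError):
    """A training operation received a single-class dataset."""


class ArchitectureError(ValueError):
    """The kernel/stride chain does not fit the input image."""
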