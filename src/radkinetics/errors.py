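"""Exception hierarchy shared across the pipeline."""


class RadkineticsError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RadkineticsError):
    """Invalid or incomplete configuration (missing offsets, bad sizes...)."""


class InvalidInputError(RadkineticsError):
    """Input data violates a precondition (empty group, single-class outcome...)."""


class EmptyROIError(InvalidInputError):
    """A mask contains no voxels where at least one was required."""


class UndefinedTextureError(RadkineticsError):
    """A texture matrix could not be formed (no valid voxel pairs / runs)."""
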