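"""Exception hierarchy shared across the package."""


class SliceMapError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(SliceMapError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(SliceMapError, ValueError):
    """Input is structurally valid but degenerate (e.g. constant foreground)."""


class NoConsensusError(SliceMapError, RuntimeError):
    """Cross-plane attribution maps admit no well-defined peak."""
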