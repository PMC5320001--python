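"""Exception types shared across the package."""


class HorseshoeError(Exception):
    """Base class for package-specific errors."""


class IdentifierError(HorseshoeError, ValueError):
    """Duplicate, unknown, or malformed feature/sample identifiers."""


class DegenerateSampleError(HorseshoeError, ValueError):
    """A sample with zero total abundance where a positive total is required."""
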