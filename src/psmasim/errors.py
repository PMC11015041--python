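"""Exception types shared across the package."""


class PsmasimError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PsmasimError):
    """An unknown or malformed configuration entry."""


class ValidationError(PsmasimError):
    """A parameter or state value violates a model invariant."""


class FormatError(PsmasimError):
    """A file does not conform to the expected on-disk format."""


class SolverError(PsmasimError):
    """A linear or time-stepping solve failed to converge."""
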