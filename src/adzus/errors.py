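"""Exception hierarchy shared across the package."""


class AdzusError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(AdzusError, ValueError):
    """An input array or argument violates a documented precondition."""


class ConfigurationError(AdzusError, ValueError):
    """A configuration object is inconsistent with the data it is applied to."""
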