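"""Exception types shared across the package."""


class RiverchemError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RiverchemError):
    """A file does not conform to the expected tabular dialect."""


class ValidationError(RiverchemError):
    """Input data violate a documented precondition."""


class ConfigError(RiverchemError):
    """A configuration table or file is malformed."""
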