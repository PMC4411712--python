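"""Exception hierarchy used across the package."""


class SistfError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SistfError):
    """A parameter or spec field violates its documented constraints."""


class ParseError(SistfError):
    """An input file could not be parsed; message carries the line/row number."""


class ConsistencyError(SistfError):
    """Internal data structures disagree (e.g. a feature outside the feature space)."""


class InputError(SistfError):
    """User-supplied data violates an interface precondition."""
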