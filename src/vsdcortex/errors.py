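"""Exception types shared across the package."""


class VsdcortexError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(VsdcortexError, ValueError):
    """A caller-supplied parameter is outside its valid domain."""


class BundleFormatError(VsdcortexError, ValueError):
    """An on-disk recording bundle is malformed; the message names the field."""


class DegenerateInputError(VsdcortexError, ValueError):
    """Input is structurally valid but numerically degenerate (e.g. I_rest <= 0)."""


class ConfigurationError(VsdcortexError, ValueError):
    """An analysis configuration cannot be satisfied by the data/geometry."""
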