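"""Exception hierarchy shared across the package."""


class TractcrowdError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TractcrowdError):
    """A file does not parse according to its declared format."""


class EmptyBundleError(TractcrowdError):
    """A bundle holds no streamlines where at least one is required."""


class SchemaError(TractcrowdError):
    """A tabular input is missing required columns or violates constraints."""


class GeometryError(TractcrowdError):
    """A geometric precondition is violated (degenerate curve, bad spacing...)."""


class ConfigError(TractcrowdError):
    """An analysis or ROI configuration is inconsistent."""


class CoreExtractionError(TractcrowdError):
    """The well-supported core of the joint parameterization is too short."""
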