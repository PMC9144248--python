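"""Exception hierarchy shared across the package."""


class MiunetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MiunetError):
    """A parameter or configuration value is out of its valid range."""


class DimensionError(MiunetError):
    """Array shapes are inconsistent with the requested operation."""


class GeometryError(MiunetError):
    """A phantom anatomy violates its geometric invariants."""


class DataError(MiunetError):
    """A dataset is empty, mismatched, or otherwise unusable."""


class FormatError(MiunetError):
    """A file does not conform to the expected schema."""
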