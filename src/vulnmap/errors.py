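"""Exception hierarchy shared across the pipeline stages."""


class VulnmapError(Exception):
    """Base class for all package errors."""


class RegistryValidationError(VulnmapError):
    """The metric registry violates a structural invariant."""


class SchemaError(VulnmapError):
    """An input table is missing required columns or has the wrong shape."""


class DataError(VulnmapError):
    """Input values are inconsistent (e.g. numerator exceeds denominator)."""


class ParameterError(VulnmapError):
    """A configuration or call parameter is out of its valid range."""


class CRSError(VulnmapError):
    """Layers do not share a projected coordinate reference system."""
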