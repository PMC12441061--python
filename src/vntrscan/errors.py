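"""Exception hierarchy shared across the package."""


class VNTRScanError(Exception):
    """Base class for all package-specific errors."""


class CatalogError(VNTRScanError):
    """A motif catalog is malformed, empty, or missing a requested motif."""


class ValidationError(VNTRScanError):
    """An input value violates a documented invariant."""


class ParameterError(VNTRScanError):
    """A configuration value is outside its admissible range."""
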