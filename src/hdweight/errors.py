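"""Exception hierarchy shared across the package."""


class HDWeightError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(HDWeightError):
    """A session table violates the CSV schema or a field-level constraint."""


class DataError(HDWeightError):
    """Valid-looking data that cannot support the requested computation."""
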