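"""Exception hierarchy shared across the package."""


class BiodistilError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BiodistilError):
    """A model/recipe/run configuration is internally inconsistent."""


class ValidationError(BiodistilError):
    """An on-disk record or in-memory example violates its contract."""


class EvaluationError(BiodistilError):
    """Metric inputs are malformed (misaligned lengths, unknown labels)."""
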