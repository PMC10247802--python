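"""Exception hierarchy shared across the package."""


class DTIError(Exception):
    """Base class for all package-specific errors."""


class MatrixFormatError(DTIError):
    """A dense-text matrix file is malformed (ragged/empty/non-numeric)."""


class DimensionError(DTIError):
    """Shapes of matrices or vectors do not agree."""


class ValidationError(DTIError):
    """A value or structure violates a documented invariant."""


class ConfigurationError(DTIError):
    """A manifest or model configuration is inconsistent."""


class SamplingError(DTIError):
    """Negative sampling cannot satisfy the requested ratio."""


class MiningError(DTIError):
    """Triplet mining is impossible (e.g. a single-class batch)."""


class MetricError(DTIError):
    """A metric is undefined for the given inputs (e.g. one-class AUC)."""
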