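"""Exception hierarchy.

Everything raised intentionally by this package derives from
:class:`RamanQuantError`, so callers (notably the CLI) can distinguish
domain failures from programming errors.
"""


class RamanQuantError(Exception):
    """Base class for all errors raised by ramanquant."""


class ValidationError(RamanQuantError):
    """Data violates a structural invariant (shapes, monotonicity, finiteness)."""


class ParseError(RamanQuantError):
    """A text input could not be parsed; the message names the offending line."""


class GridMismatchError(ValidationError):
    """Spectra that must share a wavenumber grid do not."""


class ConfigError(RamanQuantError):
    """A configuration value is invalid or inconsistent."""


class RangeError(RamanQuantError):
    """A requested wavenumber range falls outside the available data."""


class NormalizationError(RamanQuantError):
    """Area normalization is undefined (zero-sum spectrum)."""


class DegenerateFitError(RamanQuantError):
    """A least-squares correction produced a degenerate multiplicative factor."""


class TrainingError(RamanQuantError):
    """Model training diverged or otherwise failed."""


class ArchiveError(RamanQuantError):
    """A model archive is missing, corrupted, or of an unsupported version."""


class CompatibilityError(RamanQuantError):
    """Input data is incompatible with a trained model's provenance."""
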