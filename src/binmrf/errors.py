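"""Exception types shared across the package."""


class BinmrfError(Exception):
    """Base class for all package-specific errors."""


class InvalidInteractionMatrixError(BinmrfError, ValueError):
    """An odds-ratio matrix violates its invariants (symmetry, positivity, shape)."""


class CapacityError(BinmrfError, ValueError):
    """A brute-force computation was requested beyond its enumeration bound."""


class PresetLookupError(BinmrfError, KeyError):
    """An unknown preset structure name was requested."""


class DegeneratePredictorError(BinmrfError, ValueError):
    """A predictor column is constant and cannot be standardized."""


class DegenerateOutcomeError(BinmrfError, ValueError):
    """An outcome vector contains a single class only."""


class ConfigurationError(BinmrfError, ValueError):
    """Method parameters are missing or inconsistent."""


class NodeSetMismatchError(BinmrfError, ValueError):
    """Two graphs being compared are defined over different node sets."""


class DataValidationError(BinmrfError, ValueError):
    """An input file violates the expected format."""
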