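"""Exception hierarchy for the hybridcyc pipeline."""


class HybridcycError(Exception):
    """Base class for all package errors."""


class DimensionError(HybridcycError):
    """Shapes or marker dimensions of related inputs disagree."""


class LayoutError(HybridcycError):
    """The marker panel layout is invalid or a required channel is missing."""


class GenerationError(HybridcycError):
    """The synthetic generator could not satisfy its constraints."""


class DegenerateImageError(HybridcycError):
    """An image is constant (zero variance) where structure is required."""


class ConsistencyError(HybridcycError):
    """Paired label masks disagree on their label sets."""


class ControlMissingError(HybridcycError):
    """A required negative/unstained control is absent."""


class PopulationMissingError(HybridcycError):
    """A validation ROI lacks a positive or negative population."""


class DivisionDegenerateError(HybridcycError):
    """A ratio denominator is zero."""


class InsufficientControlError(HybridcycError):
    """Too few control cells to derive gating thresholds."""


class GatingError(HybridcycError):
    """A marker required for gating has no threshold or call column."""


class NormalizationError(HybridcycError):
    """Z-score normalization scope is degenerate (fewer than two rows)."""


class ParameterError(HybridcycError):
    """A clustering / model-selection parameter is out of range."""


class ModelIntegrityError(HybridcycError):
    """A fitted cluster model violates its own invariants."""


class AlignmentError(HybridcycError):
    """Profiles to be correlated do not share an identical marker order."""


class EmptySpecimenError(HybridcycError):
    """A summary was requested over zero cells."""


class ConfigError(HybridcycError):
    """A pipeline configuration file failed validation."""
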