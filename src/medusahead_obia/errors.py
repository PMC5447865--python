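"""Exception hierarchy shared across the pipeline."""


class MedusaheadObiaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MedusaheadObiaError):
    """A config object is internally inconsistent (e.g. palette missing a class)."""


class BandError(MedusaheadObiaError):
    """A required raster band/layer is absent."""


class DegenerateInputError(MedusaheadObiaError):
    """Input lacks the variation the operation needs (constant layer, too few values)."""


class ParameterError(MedusaheadObiaError):
    """An operation parameter is out of its admissible range."""


class GeometryError(MedusaheadObiaError):
    """A geometry falls outside the raster extent or is otherwise invalid."""


class AlignmentError(MedusaheadObiaError):
    """Two rasters that must share a grid do not."""


class SamplingError(MedusaheadObiaError):
    """Not enough candidate samples to honour the requested design."""

    def __init__(self, message: str, deficient_class: str | None = None):
        super().__init__(message)
        self.deficient_class = deficient_class


class TrainingError(MedusaheadObiaError):
    """A class required for supervised training has no training objects."""

    def __init__(self, message: str, missing_class: str | None = None):
        super().__init__(message)
        self.missing_class = missing_class


class SchemeError(MedusaheadObiaError):
    """A class scheme does not contain a class an operation requires."""


class EmptyRegionError(MedusaheadObiaError):
    """A per-region statistic was requested for an empty region."""
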