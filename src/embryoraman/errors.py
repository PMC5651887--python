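"""Exception hierarchy for the pipeline."""


class RamanPipelineError(Exception):
    """Base class for all package errors."""


class ConfigError(RamanPipelineError):
    """An invalid configuration value; the message names the offending field."""


class FormatError(RamanPipelineError):
    """A spectrum or manifest file could not be parsed or validated."""


class AssemblyError(RamanPipelineError):
    """A cohort could not be assembled from its manifest."""


class CalibrationError(RamanPipelineError):
    """Wavenumber calibration failed (too few matched peaks, non-monotone map)."""


class NormalizationError(RamanPipelineError):
    """Max-normalization hit a non-positive maximum (failed baseline correction)."""


class FittingError(RamanPipelineError):
    """Band seeding or nonlinear fitting failed."""


class MissingBandError(FittingError):
    """A requested nominal band is absent from a fit (or has zero area)."""


class PipelineError(RamanPipelineError):
    """A multi-stage pipeline step failed irrecoverably."""
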