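"""Exception types raised across the pipeline."""


class EwasRFError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EwasRFError, ValueError):
    """An invalid simulation or pipeline configuration."""


class DegenerateInputError(EwasRFError, ValueError):
    """Input is structurally valid but degenerate (all-zero intensities,
    single-class outcome, constant column, ...)."""


class MissingAnnotationError(EwasRFError, KeyError):
    """A probe present in the dataset has no manifest record."""


class SeparationError(EwasRFError, RuntimeError):
    """Complete or quasi-complete separation in a logistic fit; the probe
    should be skipped and logged rather than reported."""


class CollinearityError(EwasRFError, ValueError):
    """Covariate design matrix is ill-conditioned; message names the columns."""


class RankDeficientError(EwasRFError, ValueError):
    """Cell-type reference columns are linearly dependent on shared probes."""
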