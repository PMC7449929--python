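"""Exception hierarchy for glutme.

All package-specific failures derive from :class:`GlutmeError` so callers can
catch one base class; parameter problems additionally derive from
``ValueError`` to behave like ordinary argument validation.
"""


class GlutmeError(Exception):
    """Base class for all glutme errors."""


class ParameterError(GlutmeError, ValueError):
    """Invalid simulation or analysis parameters."""


class EmptyGeneSetError(GlutmeError):
    """A gene set has no overlap with the expression matrix."""


class DegenerateGeneSetError(GlutmeError):
    """A gene set covers every gene in the matrix; the running-sum statistic is undefined."""


class DegenerateInputError(GlutmeError):
    """Input with no usable variation (constant vector, zero variance, ...)."""


class NoValleyError(GlutmeError):
    """Density curve is unimodal; no between-mode valley to threshold on."""


class SegmentationError(GlutmeError):
    """Tumor segmentation produced an empty mask or an unusable reference region."""


class SurvivalModelError(GlutmeError):
    """Survival model could not be estimated (non-convergence, monotone likelihood, no events)."""
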