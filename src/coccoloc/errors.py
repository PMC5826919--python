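"""Exception hierarchy for the coccoloc pipeline.

Every stage raises a subclass of :class:`CoccolocError`, so callers can
catch pipeline failures without masking programming errors.
"""


class CoccolocError(Exception):
    """Base class for all coccoloc errors."""


class GeometryError(CoccolocError):
    """A cell or ROI does not fit the image geometry (out of frame, overlap)."""


class FormatError(CoccolocError):
    """An input file could not be read in a supported format."""


class ValidationError(CoccolocError):
    """An annotation record is inconsistent with its image."""


class CentringError(CoccolocError):
    """Cell-centre refinement failed (e.g. empty window after thresholding)."""


class EstimationError(CoccolocError):
    """A geometric estimate (e.g. cell radius) could not be formed."""


class StatisticError(CoccolocError):
    """A statistic is undefined for the given input (e.g. zero-mean profile)."""


class FitError(CoccolocError):
    """A model fit could not be performed at all (distinct from non-convergence)."""


class ThresholdError(CoccolocError):
    """Automatic thresholding is undefined (e.g. constant image)."""


class ParameterError(CoccolocError):
    """A user-supplied parameter is outside its valid range."""
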