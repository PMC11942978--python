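"""Exception hierarchy.

Every failure mode the analysis modules can raise derives from
:class:`EchoNodeError`, so callers (and the CLI) can distinguish bad input
(subclasses of :class:`InputError`) from analysis failures
(subclasses of :class:`AnalysisError`).
"""


class EchoNodeError(Exception):
    """Base class for all package errors."""


class InputError(EchoNodeError):
    """Invalid input data or parameters."""


class AnalysisError(EchoNodeError):
    """An analysis step could not produce a result."""


class InvalidContourError(InputError):
    """Contour with fewer than 3 points, duplicates, or out of bounds."""


class EmptyMaskError(InputError):
    """Binary mask contains no foreground pixel."""


class ModalityError(InputError):
    """Image modality does not match the requested analysis."""


class AnnotationError(InputError):
    """Malformed or unsupported annotation file content."""


class DegenerateShapeError(AnalysisError):
    """Contour is collinear or otherwise has no usable 2-D extent."""


class InvalidMeasureError(InputError):
    """A measured quantity is outside its physically valid range."""


class TooFewPointsError(InputError):
    """Operation requires more contour points than were supplied."""


class FitFailureError(AnalysisError):
    """Model fit (e.g. direct ellipse fit) failed on pathological input."""


class NoValidProbeError(AnalysisError):
    """All sharpness probes left the image frame."""


class UndefinedPositionError(AnalysisError):
    """Vascularity position undefined: no colored pixel inside the mask."""


class DetectionFailureError(AnalysisError):
    """Ultrasound content region could not be located in the frame."""


class NoElastogramError(AnalysisError):
    """Neither half of the frame contains colored elastogram pixels."""


class SideTieError(AnalysisError):
    """Left and right halves contain equal colored-pixel counts."""


class TranslationOutOfBoundsError(AnalysisError):
    """Translated contour would leave the image frame."""


class UndefinedMetricError(AnalysisError):
    """Evaluation metric has an empty denominator."""


class InvalidParamsError(InputError):
    """Phantom or split parameters outside their valid ranges."""
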