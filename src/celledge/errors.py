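"""Exception and warning types used across the pipeline."""


class CellEdgeError(Exception):
    """Base class for pipeline errors."""


class ParameterError(CellEdgeError, ValueError):
    """An argument violates a documented invariant; the message names the field."""


class DimensionError(CellEdgeError, ValueError):
    """Mismatched array shapes or frame counts between pipeline stages."""


class SegmentationError(CellEdgeError):
    """Cell segmentation failed for a frame; the message carries the frame index."""


class BoundaryError(CellEdgeError):
    """Boundary extraction failed (e.g. mask touches the image border)."""


class DegenerateBaselineError(CellEdgeError, ZeroDivisionError):
    """Baseline denominator of an activity normalization is zero."""


class DegenerateControlError(CellEdgeError):
    """Control enrichment ratio is non-positive; normalization undefined."""


class WindowError(CellEdgeError, ValueError):
    """Response window extends outside the recorded trace."""


class FormatError(CellEdgeError):
    """Input files are inconsistent (channel shapes, frame counts)."""


class EmptyRegionWarning(UserWarning):
    """A measurement region was empty; the value is imputed or reported missing."""
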