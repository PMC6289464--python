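"""Exception types raised by the analysis stages."""


class ShapeMismatchError(ValueError):
    """Arrays that must be aligned (windows, masks, maps) have different shapes."""


class DegenerateMapError(ValueError):
    """A net map cannot be grey-quantized (constant values, too few pixels)."""


class DegenerateHistogramError(ValueError):
    """A grey histogram has zero variance; the Gaussian prior is undefined."""


class WorkflowError(RuntimeError):
    """A workflow stage is inapplicable (e.g. no entropy peak above g0 for workflow B)."""
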