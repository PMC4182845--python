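"""Typed errors raised by the mulchres pipeline."""


class MulchresError(Exception):
    """Base class for all mulchres-specific errors."""


class InputError(MulchresError, ValueError):
    """Invalid input data (non-finite pixels, out-of-range parameters)."""


class DegenerateHistogramError(MulchresError, ValueError):
    """Histogram has mass in fewer than two distinct bins; no two-class
    split exists."""


class DegeneratePlaneError(MulchresError, ValueError):
    """Saturation plane is constant after quantization; no two-class
    split exists."""


class ConvergenceError(MulchresError, RuntimeError):
    """An iterative threshold search failed to converge."""
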