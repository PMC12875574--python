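"""Exception types shared across the package."""


class OsteographError(Exception):
    """Base class for all package-specific errors."""


class FormatError(OsteographError, ValueError):
    """An input file or array is not in a supported layout."""


class ValidationError(OsteographError, ValueError):
    """A value violates a documented contract (shape, range, class set)."""


class ParameterError(OsteographError, ValueError):
    """A parameter combination is invalid (e.g. canny_low >= canny_high)."""


class DegenerateInputError(OsteographError, ValueError):
    """The input is degenerate for the requested operation (e.g. constant
    image passed to Otsu thresholding)."""


class GenerationError(OsteographError, RuntimeError):
    """The synthetic-scene sampler could not satisfy its constraints within
    the bounded number of retries (e.g. infeasible packing)."""


class UndefinedValueError(OsteographError, ValueError):
    """A derived quantity is mathematically undefined for the given input
    (e.g. percent change relative to a zero mean)."""
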