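"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """An option value is outside its documented domain."""


class DegenerateInputError(ValueError):
    """The input carries no usable signal (e.g. constant image, all-zero gradients)."""


class ShapeError(ValueError):
    """Array shapes or image bounds are inconsistent."""
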