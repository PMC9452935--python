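class ConfigurationError(ValueError):
    """An architectural or training configuration is internally inconsistent."""


class ShapeError(ValueError):
    """Tensor shapes are incompatible with the requested operation."""
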