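class ConfigurationError(ValueError):
    """Invalid model / pipeline configuration."""


class ShapeError(ValueError):
    """Incompatible array shapes or sizes."""
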