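"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A user-supplied parameter or path is invalid."""


class ShapeError(ValueError):
    """An array does not have the shape an operation requires."""


class TrainingDiverged(RuntimeError):
    """A loss or gradient became non-finite during training."""
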