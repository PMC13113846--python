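"""Exception types shared across the pipeline."""


class InvalidParameterError(ValueError):
    """A configuration value violates its documented constraint."""


class InvalidInputError(ValueError):
    """A data argument violates a precondition (shape, range, class content)."""


class DegenerateInputError(ValueError):
    """The input is formally valid but carries no usable information
    (constant signal, zero-variance window, single-class labels)."""
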