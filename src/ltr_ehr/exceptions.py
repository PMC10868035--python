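"""Package-level exception types.

All invalid-argument conditions raise :class:`InvalidArgumentError` (a
``ValueError``) so callers can catch one family; statistically degenerate
inputs (constant labels, single-class data, no positive pairs, zero pooled
SD) raise :class:`DegenerateInputError`.
"""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(ValueError):
    """The input is structurally valid but statistically degenerate."""


class MissingCodeError(KeyError):
    """A medical code is absent from the vocabulary/embedding."""

    def __init__(self, code: str):
        super().__init__(code)
        self.code = code

    def __str__(self) -> str:  # KeyError would repr-quote the message
        return f"medical code not in vocabulary: {self.code!r}"
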