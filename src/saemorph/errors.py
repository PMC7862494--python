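"""Exception types shared across the package."""


class DomainError(ValueError):
    """An input lies outside the mathematical domain of an operation."""


class InvalidContourError(ValueError):
    """A polygon cannot be measured (too few vertices, degenerate, zero area)."""
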