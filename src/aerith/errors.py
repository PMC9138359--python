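"""Exception types shared across the package."""


class ModelFormatError(ValueError):
    """A model file could not be parsed, or violates a structural invariant."""


class NotExchangeReactionError(ValueError):
    """An operation expected an exchange (boundary) reaction id."""


class InfeasibleModelError(RuntimeError):
    """The initial model is infeasible under the configured growth floor."""


class EnumerationBudgetError(RuntimeError):
    """A combinatorial enumeration would exceed its stated budget."""
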