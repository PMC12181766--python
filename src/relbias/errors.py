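"""Exception types shared across the package."""


class DomainError(ValueError):
    """A parameter lies outside the domain on which the model is defined."""


class SingularityError(DomainError):
    """A denominator of a partial-correlation expression is (numerically) zero.

    Raised instead of silently clipping: the limits at the boundary of the
    parameter space are reachable only by explicit evaluation at 1 - eps.
    """


class InfeasibleDesignError(ValueError):
    """No design on the search grid satisfies the budget constraint."""
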