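"""Exception types shared across the package."""


class ValidationError(ValueError):
    """A parameter object or input array violates its invariants."""


class DomainError(ValueError):
    """A numeric argument lies outside the physical domain of an operation."""


class DegenerateNoiseError(RuntimeError):
    """The noise region has (near-)zero standard deviation.

    Raised instead of letting an SNR computation propagate infinities.
    """
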