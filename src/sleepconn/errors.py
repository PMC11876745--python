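"""Package-specific exceptions."""


class InsufficientSignalError(ValueError):
    """Raised when a respiration trace carries too little structure to code.

    Breath detection requires at least three breath events; traces failing
    this (flat channels, detached pressure pads) are excluded from coding
    rather than guessed at.
    """


class GenerationError(RuntimeError):
    """Raised when a synthetic-data request is infeasible.

    Examples: functional runs that cannot be packed into the session, or an
    injected edge effect that breaks positive definiteness of the target
    correlation matrix.
    """
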