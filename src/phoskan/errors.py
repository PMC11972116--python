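"""Exception hierarchy shared across the package."""


class PhosKANError(ValueError):
    """Base class for all data-contract violations raised by phoskan."""


class InvalidCodonError(PhosKANError):
    """A codon is not three characters over {A, C, G, T, U}."""


class InvalidResidueError(PhosKANError):
    """A residue letter is outside the accepted amino-acid alphabet."""


class FrameError(PhosKANError):
    """A coding sequence whose length is not a multiple of three."""


class VerificationFailure(PhosKANError):
    """A CDS/protein pair rejected by the reverse-translation filter.

    Attributes
    ----------
    reason : str
        Machine-readable rejection category.
    identity_percent : float or None
        Global-alignment identity of the translated CDS against the
        protein, when an alignment was performed before rejection.
    """

    def __init__(self, message, reason, identity_percent=None):
        super().__init__(message)
        self.reason = reason
        self.identity_percent = identity_percent


class ContractError(PhosKANError):
    """A shape or interface contract violated by a component."""
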