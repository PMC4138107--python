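"""Exception hierarchy shared across the pipeline."""


class PtpError(Exception):
    """Base class for all errors raised by this package."""


class InvalidResidueError(PtpError):
    """A sequence contains a character outside the amino-acid alphabet."""

    def __init__(self, residue: str, position: int | None = None, context: str = ""):
        self.residue = residue
        self.position = position
        where = f" at position {position}" if position is not None else ""
        ctx = f" in {context}" if context else ""
        super().__init__(f"invalid residue {residue!r}{where}{ctx}")


class ValidationError(PtpError):
    """Input data violates a documented format or range requirement."""


class ContractError(PtpError):
    """An API precondition was violated by the caller."""


class ConfigurationError(PtpError):
    """The pipeline configuration (motif registry, windows, ...) is unusable."""
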