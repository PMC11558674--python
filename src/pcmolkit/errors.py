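"""Exception hierarchy shared across the package."""


class PcmolkitError(Exception):
    """Base class for all package-specific errors."""


class NotFoundError(PcmolkitError, KeyError):
    """A requested accession or resource does not exist."""


class FormatError(PcmolkitError, ValueError):
    """A container or table violates its declared format."""


class ValidationError(PcmolkitError, ValueError):
    """Data violates a domain invariant (non-finite entries, bad shapes...)."""


class ConfigurationError(PcmolkitError, ValueError):
    """Inconsistent or unusable configuration / arguments."""


class SmilesParseError(PcmolkitError, ValueError):
    """A SMILES string could not be parsed into a molecule."""

    def __init__(self, smiles: str, reason: str = "unparseable SMILES"):
        self.smiles = smiles
        super().__init__(f"{reason}: {smiles!r}")


class DomainError(PcmolkitError, ValueError):
    """A numeric argument lies outside the operation's domain."""


class TokenizationError(PcmolkitError, ValueError):
    """Encoding or decoding a token sequence failed."""


class ContractError(PcmolkitError, ValueError):
    """A model input violates a shape or length contract."""
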