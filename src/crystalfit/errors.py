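"""Exception hierarchy shared across the package."""


class CrystalfitError(Exception):
    """Base class for all package-specific errors."""


class InvalidLatticeError(CrystalfitError):
    """Cell parameters describe a degenerate or impossible lattice."""


class SpecialPositionError(CrystalfitError):
    """Symmetry expansion produced coinciding images (special position)."""


class OverlapError(CrystalfitError):
    """Interatomic distance fell below the hard overlap bound."""


class NeutralityError(CrystalfitError):
    """Unit cell carries a non-zero net charge."""


class ConsistencyError(CrystalfitError):
    """Mismatched inputs (atom counts, crystal systems, vector lengths)."""


class ParseError(CrystalfitError):
    """Malformed or unsupported input file."""


class DomainError(CrystalfitError):
    """Argument outside the mathematical domain of an operation."""


class SensitivityUnavailableError(CrystalfitError):
    """Hessian at the reported minimum is singular or indefinite."""


class GenerationError(CrystalfitError):
    """Synthetic structure generation failed after bounded retries."""


class ConfigError(CrystalfitError):
    """Invalid or incomplete configuration."""
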