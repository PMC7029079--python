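"""Exception hierarchy used across the pipeline."""


class PlasticlimError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PlasticlimError, ValueError):
    """Input file does not conform to the expected tabular format."""


class IntegrityError(PlasticlimError, ValueError):
    """Input table violates a structural invariant (duplicates, negatives)."""


class SiteNotFoundError(PlasticlimError, KeyError):
    """Requested site_id is absent from the table."""


class InsufficientDataError(PlasticlimError, ValueError):
    """Too few complete years to run the requested computation."""


class DegenerateInputError(PlasticlimError, ValueError):
    """Series has zero variance (or another degeneracy) where variation is required."""


class DomainError(PlasticlimError, ValueError):
    """Parameter outside its mathematically valid domain."""
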