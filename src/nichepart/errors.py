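"""Exception hierarchy shared across the package.

All errors derive from :class:`NichepartError` so callers can catch the
package's failures with a single except clause; each subclass also derives
from the closest builtin (ValueError/KeyError) for idiomatic handling.
"""


class NichepartError(Exception):
    """Base class for all nichepart errors."""


class SchemaError(NichepartError, ValueError):
    """A delimited-text input is missing a required column."""


class ParseError(NichepartError, ValueError):
    """A cell could not be parsed; the message cites the offending row."""


class ValidationError(NichepartError, ValueError):
    """Records violate a dataset invariant (duplicates, non-finite values)."""


class DegenerateTissueError(NichepartError, ValueError):
    """A tissue has too few records or zero spread to be standardised."""


class MatrixError(NichepartError, ValueError):
    """A covariance matrix is asymmetric or not positive semi-definite."""


class IdentifiabilityError(NichepartError, ValueError):
    """The design cannot separate between- from within-individual variance."""


class PairingError(NichepartError, ValueError):
    """Draw sequences that must be index-paired have unequal lengths."""


class DegenerateEllipseError(NichepartError, ValueError):
    """An ellipse with singular covariance has no area."""


class TreeError(NichepartError, ValueError):
    """A phylogenetic tree is malformed (missing lengths, duplicate tips)."""


class CoverageError(NichepartError, ValueError):
    """Census species are missing from the phylogenetic distance matrix."""


class ConfigurationError(NichepartError, ValueError):
    """Required groups/seasons are absent from the supplied inputs."""


class UndefinedDiversityError(NichepartError, ValueError):
    """A diversity index is undefined (e.g. all counts zero)."""


class UndefinedPSRFError(NichepartError, ValueError):
    """The Gelman-Rubin statistic is undefined (no within-chain variance)."""
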