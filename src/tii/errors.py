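"""Exception hierarchy shared across the package.

Every error raised on purpose derives from :class:`TIIError`, so callers
(including the CLI) can distinguish anticipated failures — bad input files,
violated preconditions, capability limits — from genuine bugs.
"""


class TIIError(Exception):
    """Base class for all anticipated errors."""


class TreeFormatError(TIIError):
    """A tree or matrix file could not be parsed under the named format."""


class ValidationError(TIIError):
    """An in-memory object violates a type invariant or precondition."""


class ArgumentError(TIIError, ValueError):
    """A parameter value is outside its documented domain."""


class TaxonLookupError(TIIError, KeyError):
    """A named taxon is absent from the object it was looked up in."""

    def __str__(self) -> str:  # KeyError quotes its repr; keep the message plain
        return self.args[0] if self.args else ""


class CapabilityError(TIIError):
    """An exact computation was requested beyond its feasibility limits."""


class GenerationError(TIIError):
    """A synthetic generator could not realize the requested object."""


class DegenerateFitError(TIIError):
    """A regression cannot be fit (e.g. zero variance in the predictor)."""
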