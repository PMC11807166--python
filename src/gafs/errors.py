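"""Exception types shared across the package.

All are ``ValueError`` subclasses so callers that only care about
"bad input" can catch one base class.
"""


class GafsError(ValueError):
    """Base class for all package-specific errors."""


class InvalidSpecError(GafsError):
    """A synthetic-data specification violates its invariants."""


class InsufficientDataError(GafsError):
    """Too few samples (or classes) to compute the requested statistic."""


class EmptySelectionError(GafsError):
    """A chromosome with no selected feature reached a mean-score computation."""


class MissingSplitError(GafsError):
    """An operation needs a train/val/test split that the dataset lacks."""


class DegenerateTestError(GafsError):
    """A statistical test cannot be carried out (e.g. all observations tied)."""


class ParseError(GafsError):
    """A delimited-text input failed validation; message names the location."""
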