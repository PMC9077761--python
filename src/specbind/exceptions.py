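"""Exception hierarchy for the specbind pipeline.

All pipeline errors derive from :class:`SpecbindError` so callers can catch
one base class; the subclasses distinguish malformed files, invariant
violations, underdetermined fits, and optimizer failure.
"""


class SpecbindError(Exception):
    """Base class for all specbind errors."""


class FormatError(SpecbindError):
    """A data file could not be parsed (missing column, empty file, ...)."""


class ValidationError(SpecbindError, ValueError):
    """A value violates a domain-type invariant (negative absorbance, ...)."""


class InsufficientDataError(SpecbindError):
    """Too few usable points to determine the requested parameters."""


class FittingError(SpecbindError):
    """Nonlinear fit failed to converge; carries the best candidate found."""

    def __init__(self, message, best_candidate=None):
        super().__init__(message)
        self.best_candidate = best_candidate
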