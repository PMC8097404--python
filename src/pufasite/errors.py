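"""Exception hierarchy for pufasite."""


class PufasiteError(Exception):
    """Base class for all package errors."""


class FormatError(PufasiteError):
    """Input file malformed or inconsistent (e.g. atom-count mismatch)."""


class AnnotationError(PufasiteError):
    """Residue/atom names could not be mapped to species/roles."""

    def __init__(self, message, offenders=()):
        super().__init__(message)
        self.offenders = tuple(offenders)


class ArgumentError(PufasiteError, ValueError):
    """Invalid argument value (non-positive box, empty selection, ...)."""


class StructureError(PufasiteError):
    """Structural inconsistency (unequal subunits, atom-count mismatch)."""


class InsufficientDataError(PufasiteError):
    """Too few observations for the requested statistic."""


class SpecError(PufasiteError):
    """Invalid synthetic-system specification."""


class CriteriaError(PufasiteError):
    """Chemical-interaction criteria cannot be applied to this system."""


class FitError(PufasiteError):
    """Curve fit failed to converge or data are degenerate."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ConfigError(PufasiteError):
    """Pipeline configuration invalid."""

    def __init__(self, message, problems=()):
        super().__init__(message)
        self.problems = list(problems)
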