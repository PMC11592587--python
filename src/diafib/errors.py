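"""Exception hierarchy shared across the package."""


class DiafibError(Exception):
    """Base class for all package errors."""


class ConfigError(DiafibError):
    """A configuration file or mapping is malformed or incomplete."""


class RowError(DiafibError):
    """A cohort input row violates a record invariant.

    Carries the offending record id and field name so callers can report
    row-level diagnostics.
    """

    def __init__(self, record_id, field, message):
        self.record_id = record_id
        self.field = field
        super().__init__(f"record {record_id!r}, field {field!r}: {message}")


class MissingDataError(DiafibError):
    """An operation needs a field that is absent; lists offending ids."""

    def __init__(self, message, ids=()):
        self.ids = list(ids)
        super().__init__(message if not self.ids else f"{message}: {self.ids}")


class DomainError(DiafibError):
    """A numeric argument lies outside the mathematical domain of a score."""


class DegenerateLabelsError(DiafibError):
    """Both outcome classes are required but only one is present."""


class AlignmentError(DiafibError):
    """Paired inputs have mismatched lengths or ids."""


class PolicyInfeasibleError(DiafibError):
    """A cut-off selection target cannot be met; carries the frontier."""

    def __init__(self, message, frontier=None):
        self.frontier = frontier
        super().__init__(message)


class SeparationError(DiafibError):
    """Perfect separation in a logistic fit, naming the covariate if known."""


class RankError(DiafibError):
    """Design matrix is rank deficient (constant or collinear covariates)."""


class BinningError(DiafibError):
    """A variable has too few distinct values for the requested binning."""


class DegenerateSplitError(DiafibError):
    """Cohort too small to produce a stratified split."""


class ValidationError(DiafibError):
    """A specification object fails its own invariants."""
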