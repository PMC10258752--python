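"""Exception hierarchy shared by all airepi modules."""


class AirepiError(Exception):
    """Base class for all errors raised by airepi."""


class FormatError(AirepiError):
    """A table does not conform to the expected layout (e.g. missing column)."""


class RowParseError(FormatError):
    """A single row failed to parse; carries the 1-based row number."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class DepthError(AirepiError):
    """Repertoire read depth is below the requested subsampling target."""

    def __init__(self, total_reads: int, target: int):
        self.total_reads = total_reads
        self.target = target
        super().__init__(
            f"repertoire has {total_reads} reads, fewer than target {target}"
        )


class EmptyRepertoireError(AirepiError):
    """An operation that needs at least one clonotype received none."""


class LocusError(AirepiError):
    """Operation applied to a repertoire of the wrong locus."""


class ValidationError(AirepiError):
    """Input values violate a documented precondition."""


class DegenerateInputError(AirepiError):
    """Input is degenerate for the requested statistic (e.g. constant vector)."""


class InsufficientDataError(AirepiError):
    """Too few observations to fit the requested model."""


class RankError(AirepiError):
    """Design matrix is rank-deficient (collinear covariates)."""


class FitError(AirepiError):
    """Model fitting failed to converge or the outcome is degenerate."""


class ScenarioError(AirepiError):
    """A simulation scenario is internally infeasible."""
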