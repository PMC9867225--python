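"""Exception hierarchy shared by all pipeline stages."""


class CLSHError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CLSHError):
    """Invalid generator or pipeline configuration."""


class DataCompletenessError(CLSHError):
    """A required (county, year, indicator) value is missing."""


class UndefinedCellError(CLSHError):
    """A grid cell has no supporting data (zero overlap / no pixels)."""

    def __init__(self, message: str, cell_ids=()):
        super().__init__(message)
        self.cell_ids = list(cell_ids)


class DomainError(CLSHError):
    """An input value is outside the mathematical domain of a formula."""


class AssemblyError(CLSHError):
    """Indicator cube assembly failed (missing series or cell-years)."""


class DegenerateIndicatorError(CLSHError):
    """An indicator is constant over the pooled sample, so min-max scaling
    is undefined."""


class DiagnosticsError(CLSHError):
    """KMO/Bartlett diagnostics cannot be computed (singular correlation)."""


class ScreeningError(CLSHError):
    """PCA screening retained fewer than two indicators."""


class WeightingError(CLSHError):
    """Weight vector cannot be formed (degenerate input or length mismatch)."""


class ContractError(CLSHError):
    """Inputs to an operation violate its interface contract."""


class ClassificationError(CLSHError):
    """Natural-breaks classification is infeasible (too few distinct values)."""


class UndefinedStatisticError(CLSHError):
    """A spatial statistic is undefined (e.g. zero variance)."""


class StageError(CLSHError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
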