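"""Named exceptions for the neurodim pipeline.

Each distinct failure mode the public API promises to signal gets its own
class so callers (and the CLI) can branch on type rather than message text.
"""


class NeurodimError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(NeurodimError, ValueError):
    """An invalid configuration value (mode names, negative scales, ...)."""


class SchemaError(NeurodimError, ValueError):
    """A table is missing required columns or has unexpected ones."""


class CohortDataError(NeurodimError, ValueError):
    """Cohort cell values are non-numeric or missing."""


class EmptyFileError(NeurodimError, ValueError):
    """An input file contains no data rows."""


class SingularCovarianceError(NeurodimError, ValueError):
    """Sample covariance matrix is singular (factor model cannot be fit)."""


class HeywoodError(NeurodimError, RuntimeError):
    """Factor scores requested from a fit containing a Heywood case."""


class RankDeficiencyError(NeurodimError, ValueError):
    """Regression design matrix is rank deficient; names offending columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(self.columns)
        )


class ConstantVectorError(NeurodimError, ValueError):
    """Pearson correlation requested for a zero-variance vector."""


class ScalingError(NeurodimError, ValueError):
    """Min-max scaling is undefined (constant column) or mismatched."""


class TrainingDivergedError(NeurodimError, RuntimeError):
    """Network weights became non-finite during training."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"training diverged (non-finite weights) at epoch {epoch}")


class StageError(NeurodimError, RuntimeError):
    """A pipeline stage failed; carries the stage name for exit codes."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause!r}")
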