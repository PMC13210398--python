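"""Exception hierarchy for mrgraph."""


class MrgraphError(Exception):
    """Base class for all mrgraph errors."""


class ModelViolationError(MrgraphError, ValueError):
    """A direct-effect graph violates the admissibility conditions
    (zero diagonal, spectral radius bounded below 1)."""


class NonConvergentDynamicsError(ModelViolationError):
    """The recursive dynamics do not converge (spectral radius >= 1)."""


class SingularMatrixError(MrgraphError, ValueError):
    """A linear system is singular or too ill-conditioned to solve.

    Carries the estimated condition number for context.
    """

    def __init__(self, message: str, condition_number: float = float("inf")):
        super().__init__(f"{message} (condition number ~ {condition_number:.3e})")
        self.condition_number = condition_number


class DegenerateScalingError(MrgraphError, ValueError):
    """A diagonal entry of the inverse MR-effect matrix is (numerically) zero,
    so the column rescaling of the graph-recovery algorithm is undefined."""


class InsufficientInstrumentsError(MrgraphError, ValueError):
    """Fewer than two instruments are available for a trait pair."""


class MonomorphicVariantError(MrgraphError, ValueError):
    """A genotype vector has zero variance, so no marginal regression exists."""


class MissingSummaryError(MrgraphError, KeyError):
    """A requested SNP/trait summary-statistic entry is absent."""


class FactorizationError(MrgraphError, ValueError):
    """A correlation matrix could not be Cholesky-factorized even after jitter."""


class EnsembleFailureError(MrgraphError, RuntimeError):
    """More than half of the perturbation replicates failed."""


class ValidationError(MrgraphError, ValueError):
    """Malformed input file or container."""
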