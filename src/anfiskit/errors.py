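"""Exception types raised across the anfiskit pipeline."""


class AnfiskitError(Exception):
    """Base class for all anfiskit errors."""


class InvalidParameterError(AnfiskitError, ValueError):
    """A numeric parameter is non-finite or outside its admissible range."""


class DegenerateCohortError(AnfiskitError, ValueError):
    """Cohort configuration rounds to zero members in a diagnostic group."""


class SchemaError(AnfiskitError, KeyError):
    """A required column is missing or a table does not match the contract."""


class EncodingError(AnfiskitError, ValueError):
    """A categorical value is not among the recognised labels."""


class ZeroRangeError(AnfiskitError, ValueError):
    """A feature is constant, so min-max scaling has zero range."""


class UnimputableColumnError(AnfiskitError, ValueError):
    """A key column is entirely missing, so its mean cannot be computed."""


class StratificationError(AnfiskitError, ValueError):
    """A class is too small to stratify into the requested partitions."""


class UndefinedMetricError(AnfiskitError, ValueError):
    """A statistic is undefined (single-class labels, zero denominator...)."""


class ModelStateError(AnfiskitError, RuntimeError):
    """An operation requires a trained model but none is available."""


class TrainingDivergedError(AnfiskitError, RuntimeError):
    """The training loss became non-finite."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"training loss non-finite at epoch {epoch}")
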