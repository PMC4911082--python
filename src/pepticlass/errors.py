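"""Exception hierarchy for the pepticlass pipeline."""


class PepticlassError(Exception):
    """Base class for all pipeline errors."""


class FormatError(PepticlassError):
    """A file could not be parsed under the declared dialect."""


class ValidationError(PepticlassError):
    """Data violated a domain invariant (negative amplitude, duplicate peak, ...)."""

    def __init__(self, message: str, rows: list[int] | None = None):
        super().__init__(message)
        self.rows = rows or []


class CalibrationError(PepticlassError):
    """Too few reference peptides matched, or residuals exceed the QC bound."""


class NormalizationError(PepticlassError):
    """Too few housekeeping peptides detected to estimate a scale factor."""


class TrainingError(PepticlassError):
    """Classifier training is impossible on the given inputs."""


class ScoringError(PepticlassError):
    """A sample cannot be scored (missing panel peptide column)."""


class ConfigError(PepticlassError):
    """A run configuration is internally inconsistent."""


class StageError(PepticlassError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
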