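"""Exception hierarchy shared across the package."""


class SensipodError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(SensipodError):
    """Input table or series violates the documented schema (missing columns,
    mismatched concentration grids, bad dtypes)."""


class InvalidInputError(SensipodError, ValueError):
    """A scalar argument is outside its admissible domain."""


class InsufficientDataError(SensipodError):
    """Fewer observations than the operation requires (e.g. < 2 h-CLAT runs)."""


class NoValidModelError(SensipodError):
    """No peptide-reactivity prediction model applies (both peptides co-eluted,
    or the cysteine peptide itself is unusable)."""


class NoReferenceError(SensipodError):
    """No in vivo study is eligible to provide a representative EC3."""


class EnsembleFailureError(SensipodError):
    """More than half of the ensemble training runs failed."""


class PipelineStageError(SensipodError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
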