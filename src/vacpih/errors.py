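"""Exception hierarchy shared across the package."""


class VacError(Exception):
    """Base class for all package-specific errors."""


class DomainError(VacError, ValueError):
    """An input value violates a physical or mathematical precondition."""


class NonPhysiologicalElastance(DomainError):
    """DAP <= End(est) * 0.9 * SAP: the single-beat Ees would be <= 0."""


class SchemaError(VacError, ValueError):
    """A tabular input is missing mandatory columns or has bad types."""


class ConfigError(VacError, ValueError):
    """A run configuration is invalid (unknown keys, missing seed, ...)."""


class NestingError(VacError, ValueError):
    """A model pair submitted as nested is not (e.g. reduced fits better)."""


class ConvergenceError(VacError, RuntimeError):
    """An iterative routine (calibration, model fit) failed to converge."""


class StageError(VacError, RuntimeError):
    """Pipeline stage failure; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
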