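"""Exception types shared across the package."""


class MotorSynError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(MotorSynError, ValueError):
    """A structural parameter violates its contract (e.g. non-positive bandwidth)."""


class DegenerateNormalizerError(MotorSynError, FloatingPointError):
    """The basis-function normalizer vanished at the evaluated phase."""


class SchemeMismatchError(MotorSynError, ValueError):
    """Coefficient arrays are inconsistent with the declared sharing scheme."""


class RankDeficiencyError(MotorSynError, ValueError):
    """The least-squares design matrix for coefficient recovery is rank deficient."""


class TrajectoryParseError(MotorSynError, ValueError):
    """A trajectory CSV could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
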