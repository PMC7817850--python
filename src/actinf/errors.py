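"""Exception hierarchy shared across the package."""


class ActinfError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ActinfError):
    """A serialized model spec is structurally malformed.

    Carries ``path``, a JSON-pointer-like string locating the offending key.
    """

    def __init__(self, message: str, path: str = "/"):
        super().__init__(f"{path}: {message}")
        self.path = path


class ModelValidationError(ActinfError):
    """A structurally well-formed model violates a probabilistic invariant."""

    def __init__(self, violations):
        self.violations = list(violations)
        lines = "; ".join(f"[{v.code}] {v.message}" for v in self.violations)
        super().__init__(f"invalid model: {lines}")


class ConfigurationError(ActinfError):
    """Inconsistent or missing configuration (modes, preferences, policies)."""


class DegenerateInputError(ActinfError):
    """An input that cannot be normalized into a proper distribution."""


class ImpossibleObservationError(ActinfError):
    """Observation has zero marginal likelihood under the current prior."""


class ConvergenceError(ActinfError):
    """Iterative inference failed to reach tolerance; carries the last iterate."""

    def __init__(self, message, last_iterate=None, trace=None):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.trace = trace
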