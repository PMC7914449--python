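"""Exception hierarchy for bilayerlab."""


class BilayerlabError(Exception):
    """Base class for all bilayerlab errors."""


class InvalidGridError(BilayerlabError):
    """Raised when a requested sampling grid is unusable (e.g. < 10 points)."""


class InvalidInputError(BilayerlabError):
    """Raised when input data violates an operation's preconditions."""


class InsufficientBaselineError(BilayerlabError):
    """Raised when exclusion windows leave too little trace for baseline fitting."""


class NegativeWaterError(BilayerlabError):
    """Raised when the derived bilayer thickness reaches or exceeds the repeat distance."""


class MissingDiagonalError(BilayerlabError, KeyError):
    """Raised when a cross-peak references a group with no diagonal volume."""

    def __init__(self, group: str):
        self.group = group
        super().__init__(f"no diagonal volume for group {group!r}")


class MissingGroupError(BilayerlabError, KeyError):
    """Raised when a required group is absent from a trajectory frame."""

    def __init__(self, group: str, frame: int):
        self.group = group
        self.frame = frame
        super().__init__(f"group {group!r} missing from frame {frame}")


class FitFailureError(BilayerlabError):
    """Raised when a nonlinear fit fails to converge from every start."""

    def __init__(self, message: str, diagnostics=None):
        self.diagnostics = diagnostics
        super().__init__(message)


class ConfigError(BilayerlabError):
    """Raised on configuration validation failure; aggregates all violations."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {v}" for v in self.violations))


class DependencyError(BilayerlabError):
    """Raised when a pipeline stage is missing an upstream output."""
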