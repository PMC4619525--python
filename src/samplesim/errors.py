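"""Exception hierarchy for samplesim.

Exit-code mapping used by the CLI: ConfigError -> 2, InfeasibleScenarioError -> 3,
I/O problems -> 4.
"""


class SampleSimError(Exception):
    """Base class for all package errors."""


class ConfigError(SampleSimError):
    """A configuration value violates its invariants."""


class ValidationError(SampleSimError):
    """A population table violates the schema or its invariants."""


class EmptyPopulationError(ValidationError):
    """A population contains no hospitals."""


class InfeasibleScenarioError(SampleSimError):
    """A scenario requests more hospitals than a stratum holds."""

    def __init__(self, stratum: str, requested: int, available: int):
        self.stratum = stratum
        self.requested = requested
        self.available = available
        super().__init__(
            f"scenario requests {requested} hospitals from stratum "
            f"{stratum!r} which holds only {available}"
        )


class RankDeficientError(SampleSimError):
    """The design matrix is rank deficient on the fitted sample."""

    def __init__(self, terms):
        self.terms = tuple(terms)
        super().__init__(
            "design matrix is rank deficient; offending term(s): "
            + ", ".join(self.terms)
        )


class NotConvergedError(SampleSimError):
    """A fit flagged non-converged was used where convergence is required."""


class MetricUndefinedError(SampleSimError):
    """An error percentage is undefined (zero population total)."""
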