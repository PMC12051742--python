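"""Exception types shared across the package."""


class CrowdemogError(Exception):
    """Base class for package errors."""


class ConfigurationError(CrowdemogError):
    """A required parameter or configuration entry is missing or malformed."""


class ValidationError(CrowdemogError):
    """A demographic model violates one or more structural invariants.

    Carries the full list of violations so callers can report them all.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class LayoutError(CrowdemogError):
    """A synthetic dataset layout is internally inconsistent."""


class LikelihoodError(CrowdemogError):
    """The composite likelihood is undefined for the given inputs."""
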