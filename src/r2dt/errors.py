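"""Exception hierarchy shared across the package."""


class R2DTError(Exception):
    """Base class for all package-specific errors."""


class DomainError(R2DTError, ValueError):
    """An input value lies outside its mathematical domain (e.g. a probability outside [0, 1])."""


class UtilityConfigError(R2DTError, ValueError):
    """A utility or design parameter violates its constraints."""


class ConfigError(R2DTError, ValueError):
    """A configuration document is malformed or violates an invariant; the message names the field."""


class ElicitationInconsistencyError(R2DTError, ValueError):
    """A stated indifference point cannot be produced by any admissible parameter value."""


class SingularSystemError(R2DTError, ValueError):
    """The linear system implied by the stated equivalences is singular or ill-conditioned."""
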