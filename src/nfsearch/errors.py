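"""Exception hierarchy shared by all nfsearch modules."""


class NFSearchError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(NFSearchError, ValueError):
    """A configuration object (schedule, protocol, mapping) violates its invariants."""


class DomainError(NFSearchError, ValueError):
    """An input value lies outside the operation's domain (bad state, bad weight)."""


class FormatError(NFSearchError, ValueError):
    """A stream or file does not conform to the expected layout."""


class GenerationError(NFSearchError, RuntimeError):
    """A random generator exhausted its retry budget without a valid output."""


class InsufficientDataError(NFSearchError, ValueError):
    """Too few samples in a statistical window to compute the requested statistic."""


class UndefinedStatisticError(NFSearchError, ValueError):
    """Degenerate data (zero variance, equal means) leaves the statistic undefined."""


class NodeBudgetExceeded(NFSearchError, RuntimeError):
    """The search expanded its node budget without reaching a goal."""
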