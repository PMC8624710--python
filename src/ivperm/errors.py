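"""Exception hierarchy for the ivperm pipeline."""


class IvpermError(Exception):
    """Base class for all ivperm errors."""


class InvalidCompoundError(IvpermError, ValueError):
    """A compound record violates its invariants (e.g. nonpositive molar mass)."""


class DomainError(IvpermError, ValueError):
    """A numeric argument is outside the operation's domain."""


class ConfigurationError(IvpermError, ValueError):
    """Inconsistent study configuration (schedule, cell geometry, registry)."""


class InputError(IvpermError, ValueError):
    """Malformed input data (misaligned lengths, negative concentrations, ...)."""


class NoSteadyStateError(IvpermError, RuntimeError):
    """No candidate regression window has a positive slope."""


class GroupingError(IvpermError, ValueError):
    """Records from different compounds/membranes mixed in one aggregate."""


class UndefinedCorrelationError(IvpermError, ValueError):
    """Pearson correlation undefined (zero variance in a series)."""


class ResolutionError(IvpermError, KeyError):
    """Compound acronyms in a dataset do not resolve against the registry."""


class SchemaError(IvpermError, ValueError):
    """A table is missing required columns."""
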