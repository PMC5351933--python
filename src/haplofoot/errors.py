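"""Exception hierarchy shared across the package."""


class HaplofootError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(HaplofootError, ValueError):
    """An invalid configuration field; the message names the field."""


class BedParseError(HaplofootError, ValueError):
    """Malformed BED input; the message carries the offending line number."""


class ValidationError(HaplofootError, ValueError):
    """An operation precondition was violated."""


class LDUndefinedError(HaplofootError, ValueError):
    """r² requested for a monomorphic variant (p = 0 or 1): LD is undefined,
    which is distinct from r² = 0."""


class SentinelNotFoundError(HaplofootError, KeyError):
    """A sentinel variant id is absent from the panel."""


class PlacementError(HaplofootError, ValueError):
    """An interval cannot be placed inside any workspace segment."""


class UndefinedStatisticError(HaplofootError, ValueError):
    """A statistic has an empty denominator (e.g. zero haplotype blocks)."""
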