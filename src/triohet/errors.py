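"""Exception hierarchy shared across the package."""


class TriohetError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(TriohetError, ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class ParseError(TriohetError, ValueError):
    """A tabular input file could not be parsed; message names the offending line."""


class UndefinedStatisticError(TriohetError, ValueError):
    """A requested statistic is undefined for the given input (zero denominator,
    constant column, missing measurement)."""
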