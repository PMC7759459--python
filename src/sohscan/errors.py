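"""Exception types shared across the package."""


class SohscanError(Exception):
    """Base class for package errors."""


class ConfigError(SohscanError, ValueError):
    """A simulation or analysis configuration violates its invariants."""


class VcfParseError(SohscanError, ValueError):
    """A VCF record could not be parsed; message names the offending line."""


class UndefinedValueError(SohscanError, ValueError):
    """A summary statistic is undefined for the given input (e.g. 0/0)."""


class DegenerateDataError(SohscanError, ValueError):
    """Input data admit no meaningful fit (e.g. zero-variance mixture input)."""
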