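"""Exception types shared across the package."""


class FormatError(ValueError):
    """An input file does not conform to the expected dialect/schema."""


class ConfigError(ValueError):
    """A configuration object or file is invalid or infeasible."""


class UsageError(ValueError):
    """An operation was called with arguments outside its contract."""
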