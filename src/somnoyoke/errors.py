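"""Exception hierarchy shared across the package."""


class SomnoyokeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SomnoyokeError):
    """Invalid parameter or configuration value."""


class DesignError(SomnoyokeError):
    """Invalid experimental design (duplicate ids, unpaired yoked flies, ...)."""


class DataError(SomnoyokeError):
    """Malformed or inconsistent input data."""
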