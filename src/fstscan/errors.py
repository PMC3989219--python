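"""Exception hierarchy for fstscan."""


class FstscanError(Exception):
    """Base class for all fstscan errors."""


class ParseError(FstscanError):
    """A file could not be parsed; the message names the offending line."""


class StructuralError(FstscanError):
    """Inputs are individually well-formed but mutually inconsistent."""


class ConfigurationError(FstscanError):
    """A parameter value is outside its valid range."""


class DomainError(FstscanError):
    """A numeric argument is outside the mathematical domain of an operation."""
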