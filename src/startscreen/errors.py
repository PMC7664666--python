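"""Exception hierarchy shared across the package."""


class StartScreenError(Exception):
    """Base class for all errors raised by this package."""


class FastaParseError(StartScreenError):
    """Malformed FASTA input (e.g. sequence text before the first header)."""


class ConfigError(StartScreenError):
    """Invalid configuration value (unknown dialect, bad geometry, ...)."""


class DomainError(StartScreenError):
    """Input outside an operation's domain (empty sequence, positive MFE, ...)."""


class BoundsError(StartScreenError):
    """Window coordinates exceed the parent sequence."""


class StructureFormatError(StartScreenError):
    """Dot-bracket string is not well formed (unbalanced brackets)."""

    def __init__(self, message: str, index: int | None = None):
        super().__init__(message)
        self.index = index


class EngineUnavailableError(StartScreenError):
    """The requested external folding engine cannot be used in this process."""
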