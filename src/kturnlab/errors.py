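"""Exception hierarchy shared across the package."""


class KTurnError(Exception):
    """Base class for all kturnlab errors."""


class ParseError(KTurnError):
    """A coordinate or alignment file could not be parsed."""


class FormatError(KTurnError):
    """An unknown or unsupported file format was requested."""


class AnnotationError(KTurnError):
    """A k-turn annotation points at a residue absent from the structure."""


class IncompleteInstanceError(KTurnError):
    """A geometric operation was asked for atoms the instance does not have."""


class AlignmentError(KTurnError):
    """An alignment is ragged or a requested column is out of range."""


class ProfileError(KTurnError):
    """A frequency profile could not be computed (e.g. zero usable rows)."""


class ConfigError(KTurnError):
    """A pipeline configuration failed validation."""
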