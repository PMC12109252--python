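"""Exception hierarchy shared by all stages of the pipeline."""


class InvadeLossError(Exception):
    """Base class for all package-specific errors."""


class FormatError(InvadeLossError):
    """Unreadable, multi-band, rotated, or otherwise unsupported file."""


class AlignmentError(InvadeLossError):
    """Rasters that must share a grid do not."""


class ConfigError(InvadeLossError):
    """Invalid parameter or scenario configuration."""


class InputError(InvadeLossError):
    """Inconsistent or missing data passed between stages."""


class DerivationError(InvadeLossError):
    """Allocation-weight derivation impossible (e.g. zero linked area)."""


class StatisticError(InvadeLossError):
    """A statistic is undefined on the given input (e.g. zero variance)."""


class IdentificationError(InvadeLossError):
    """Panel lacks the variation needed to identify the treatment effect."""
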