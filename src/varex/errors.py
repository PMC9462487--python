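"""Exception hierarchy shared across the toolkit."""


class VarexError(Exception):
    """Base class for all toolkit errors."""


class FormatError(VarexError):
    """A file violates the supported format subset (e.g. VCF without GT,
    multi-allelic ALT, malformed header)."""


class DataError(VarexError):
    """Well-formed file, invalid content (negative counts, duplicate genes,
    non-integral values, empty table)."""


class ConfigError(VarexError):
    """Invalid analysis or simulation configuration."""


class SimulationError(VarexError):
    """A simulation cannot produce the requested output (e.g. unattainable
    case quota)."""


class InputError(VarexError):
    """Invalid arguments to an analysis operation."""


class DegenerateTableError(InputError):
    """A 2x2 allele table has no called samples in a group."""


class ContrastError(InputError):
    """A requested group contrast has too few samples; the message names
    the offending group."""


class NormalizationError(InputError):
    """Median-of-ratios normalization has no usable reference genes."""
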