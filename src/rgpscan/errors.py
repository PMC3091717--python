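"""Exception hierarchy for rgpscan."""


class RgpscanError(Exception):
    """Base class for all rgpscan errors."""


class FormatError(RgpscanError):
    """Input file does not parse under the named standard."""


class EmptyAnnotationError(RgpscanError):
    """Genome file contains no gene features."""


class UnknownRepliconError(RgpscanError):
    """A result references a replicon id not present in the genome."""


class ParameterError(RgpscanError):
    """Invalid parameter value or combination."""


class InputError(RgpscanError):
    """Degenerate or invalid operation input (e.g. empty protein)."""


class ConfigError(RgpscanError):
    """Invalid run or simulation configuration."""
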