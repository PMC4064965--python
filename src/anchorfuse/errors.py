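"""Exception hierarchy shared across the toolkit."""


class AnchorfuseError(Exception):
    """Base class for all anchorfuse errors."""


class AlphabetError(AnchorfuseError):
    """Sequence contains characters outside the {A,C,G,T,N} alphabet."""


class FormatError(AnchorfuseError):
    """Malformed FASTA/FASTQ/TSV input."""


class CoordinateError(AnchorfuseError):
    """A 1-based region falls outside its transcript."""


class ProbeError(AnchorfuseError):
    """An anchor probe cannot be built from the requested region."""


class ParameterError(AnchorfuseError):
    """An operation was called with inconsistent parameters."""


class JunctionInferenceError(AnchorfuseError):
    """Junction consensus cannot be computed (e.g. no chimeric calls)."""


class PrimerSiteError(AnchorfuseError):
    """A primer has no exact site on the template."""


class OrientationError(AnchorfuseError):
    """Primer sites exist but in PCR-incompatible orientation."""


class ConfigError(AnchorfuseError):
    """Invalid simulation configuration."""
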