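"""Exception hierarchy.

Every error raised on a user-facing path derives from :class:`StrainSigError`
so the CLI can map them to exit code 1; programming errors propagate as-is.
"""

from __future__ import annotations


class StrainSigError(Exception):
    """Base class for all errors raised by strainsig."""


class InvalidAlphabetError(StrainSigError, ValueError):
    """A sequence window contained a character outside {A, C, G, T}."""


class InvalidParameterError(StrainSigError, ValueError):
    """A parameter value is outside its documented domain."""


class InvalidEncodingError(StrainSigError, ValueError):
    """A packed n-gram value is not representable for its gram length."""


class ModelTooSmallError(StrainSigError, ValueError):
    """A signature model needs at least two genomes."""


class ConfigurationError(StrainSigError):
    """Inconsistent run configuration (duplicate ids, n/orientation mismatch...)."""


class FastaError(StrainSigError):
    """A FASTA source could not be read or was empty."""


class FastqParseError(StrainSigError):
    """A FASTQ record could not be parsed; carries file and record index."""

    def __init__(self, message: str, path: str | None = None, record_index: int | None = None):
        super().__init__(message)
        self.path = path
        self.record_index = record_index


class ModelFormatError(StrainSigError):
    """Unsupported model file (bad magic bytes or unknown format version)."""


class CorruptModelError(ModelFormatError):
    """Model file is truncated or internally inconsistent."""


class CalibrationError(StrainSigError):
    """Score distributions are inseparable; carries both curves for inspection."""

    def __init__(self, message: str, positive_curve=None, negative_curve=None):
        super().__init__(message)
        self.positive_curve = positive_curve
        self.negative_curve = negative_curve
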