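"""Exception types shared across the package."""


class EtpfamError(Exception):
    """Base class for all package-specific errors."""


class FastaParseError(EtpfamError):
    """Raised for malformed or inconsistent FASTA input."""


class ConfigurationError(EtpfamError):
    """Raised for invalid or unknown configuration values."""


class LookupKeyError(EtpfamError, KeyError):
    """Raised when an id is missing from a store or table."""


class NotFittedError(EtpfamError):
    """Raised when a learned component is used before fitting."""
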