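"""Exception hierarchy for aeiquant."""


class AeiQuantError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AeiQuantError, ValueError):
    """A simulation or analysis configuration violates its invariants."""


class FormatError(AeiQuantError, ValueError):
    """A tabular input file is malformed (header, duplicates, bad values)."""


class InsufficientDataError(AeiQuantError, ValueError):
    """Too few usable observations to compute the requested quantity."""


class UnknownSnpError(AeiQuantError, KeyError):
    """A SNP identifier is not in the declared panel."""
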