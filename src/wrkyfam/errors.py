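"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, FormatError -> 3,
InternalError -> 4.
"""


class WrkyfamError(Exception):
    """Base class for all package errors."""


class ConfigError(WrkyfamError):
    """Invalid or inconsistent configuration."""


class FormatError(WrkyfamError):
    """Malformed input data (FASTA/GFF3/TSV/signature syntax...)."""


class FixtureError(WrkyfamError):
    """A packaged fixture is missing or fails its checksum."""


class InternalError(WrkyfamError):
    """An internal invariant was violated; indicates a bug."""
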