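"""Exception hierarchy.

All archminer errors derive from :class:`ArchminerError` so callers can
catch the package's failures with one clause while letting genuine bugs
(TypeError, etc.) propagate.
"""


class ArchminerError(Exception):
    """Base class for all archminer errors."""


class FormatError(ArchminerError):
    """Malformed input file (FASTA, domtblout, profile container)."""


class DatasetIntegrityError(ArchminerError):
    """Dataset violates an invariant (duplicate ids, unknown references)."""


class SchemaError(ArchminerError):
    """Rules file violates the rules schema."""


class UsageError(ArchminerError):
    """An operation was called outside its contract."""


class BackendUnavailableError(ArchminerError):
    """The requested search backend cannot run in this environment."""
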