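"""Exception hierarchy for the grass codec.

Every error raised on a user-facing path derives from :class:`GrassError`,
so callers (and the CLI) can catch one type. Contract violations between
internal stages raise :class:`InternalContractError` — seeing one means a
bug in the codec, not bad input.
"""


class GrassError(Exception):
    """Base class for all grass codec errors."""


class EmptyInputError(GrassError):
    """The input file is empty where a sequence was required."""


class MalformedFastaError(GrassError):
    """Structurally invalid FASTA/multi-FASTA (stray '>', empty record, blank line)."""


class UnsupportedByteError(GrassError):
    """Input contains bytes the codec cannot represent losslessly."""


class InvalidRunError(GrassError):
    """Lowercase runs overlap or are not strictly increasing."""


class InvalidSpecialError(GrassError):
    """A special-character entry names a letter of the record's core alphabet."""


class InvalidLayoutError(GrassError):
    """A line length is non-positive."""


class CorruptStreamError(GrassError):
    """A serialized stream is truncated or internally inconsistent."""


class NotAGrassArchiveError(GrassError):
    """The file does not start with the grass archive magic."""


class UnsupportedVersionError(GrassError):
    """Archive version is newer than this implementation."""


class CorruptArchiveError(GrassError):
    """Archive is truncated or fails its checksum."""


class ConfigurationError(GrassError):
    """Unknown backend id or invalid configuration value."""


class ParameterError(GrassError):
    """Contradictory synthetic-generator parameters."""


class EmptyCorpusError(GrassError):
    """A corpus metric was requested for an empty file list."""


class InternalContractError(GrassError):
    """An internal stage received data violating its preconditions (a bug)."""
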