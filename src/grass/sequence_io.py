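"""Phase 1: parse raw/FASTA/multi-FASTA input and separate the streams.

The preprocessing stage splits an input file into a core nucleotide stream
(uppercase A, C, G, T/U, N — the "F1" stream fed to the grammar codec) and
auxiliary metadata ("F2"): identifiers, lowercase-run tuples, special
IUPAC characters with their positions, the line-wrap layout and per-record
block lengths. The split is information-preserving:
:func:`restore_records` rebuilds the original bytes exactly.

Coordinates are 0-based over the full per-record residue string *before*
special characters are removed; for a record with ``n_seq`` residues of
which ``n_spl`` are special, the core contributes ``n_tar = n_seq - n_spl``
characters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

from .aux_coding import (
    AuxiliaryStreams,
    CaseRun,
    SpecialEntry,
    decode_case_runs,
    decode_specials,
    delta_block_lengths,
    encode_case_runs,
    encode_specials,
    expand_line_lengths,
    rle_line_lengths,
    undelta_block_lengths,
)
from .errors import (
    CorruptStreamError,
    EmptyInputError,
    MalformedFastaError,
    UnsupportedByteError,
)

__all__ = [
    "DNA_CORE",
    "RNA_CORE",
    "SequenceRecord",
    "ParsedInput",
    "ExtractionResult",
    "AuxiliaryStreams",
    "CaseRun",
    "SpecialEntry",
    "detect_format",
    "parse_input",
    "extract_streams",
    "restore_records",
]

DNA_CORE = "ACGTN"
RNA_CORE = "ACGUN"

_PRINTABLE = set(range(0x20, 0x7F))


@dataclass
class SequenceRecord:
    """One input record as laid out in the file.

    ``identifier`` is the verbatim header line (with its leading '>'),
    or ``None`` for raw input. ``line_lengths`` records how the residues
    were wrapped; their sum equals ``len(residues)``.
    """

    identifier: str | None
    residues: str
    line_lengths: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if sum(self.line_lengths) != len(self.residues):
            raise MalformedFastaError("line lengths do not sum to residue count")
        if self.identifier is not None and not self.identifier.startswith(">"):
            raise MalformedFastaError("identifier must start with '>'")


class ParsedInput(NamedTuple):
    records: list[SequenceRecord]
    eol: str  # "lf" | "crlf"
    final_newline: bool
    format: str  # "raw" | "fasta" | "multifasta"


@dataclass
class ExtractionResult:
    """Output of Phase-1 extraction over all records."""

    core: str
    aux: AuxiliaryStreams
    n_seq: int
    n_spl: int

    @property
    def n_tar(self) -> int:
        return self.n_seq - self.n_spl


def detect_format(input_bytes: bytes) -> str:
    """Classify input as ``raw``, ``fasta`` (one header) or ``multifasta``."""
    if not input_bytes:
        raise EmptyInputError("cannot detect the format of an empty input")
    try:
        text = input_bytes.decode("ascii")
    except UnicodeDecodeError as exc:
        raise UnsupportedByteError(f"input is not ASCII text: {exc}") from None
    headers = sum(1 for line in text.split("\n") if line.startswith(">"))
    if headers >= 2:
        return "multifasta"
    if headers == 1:
        return "fasta"
    return "raw"


def _split_lines(input_bytes: bytes) -> tuple[list[str], str, bool]:
    """Decode, validate EOL consistency and split into logical lines."""
    try:
        text = input_bytes.decode("ascii")
    except UnicodeDecodeError as exc:
        raise UnsupportedByteError(f"input is not ASCII text: {exc}") from None
    for ch in text:
        if ord(ch) not in _PRINTABLE and ch not in "\r\n\t":
            raise UnsupportedByteError(f"unsupported byte {ord(ch):#04x} in input")
    crlf = text.count("\r\n")
    bare_cr = text.count("\r") - crlf
    if bare_cr:
        raise UnsupportedByteError("bare carriage return in input")
    if crlf:
        if text.count("\n") != crlf:
            raise UnsupportedByteError("mixed LF and CRLF line endings")
        eol = "crlf"
        text = text.replace("\r\n", "\n")
    else:
        eol = "lf"
    final_newline = text.endswith("\n")
    lines = text.split("\n")
    if final_newline:
        lines.pop()
    return lines, eol, final_newline


def _check_sequence_line(line: str) -> None:
    if not line:
        raise MalformedFastaError("blank line inside a sequence")
    for ch in line:
        if ch == ">":
            raise MalformedFastaError("'>' inside a sequence line")
        if not ch.isalpha():
            raise UnsupportedByteError(f"non-letter residue {ch!r}")


def parse_input(input_bytes: bytes) -> ParsedInput:
    """Parse raw/FASTA/multi-FASTA bytes into records plus layout flags.

    The parse is lossless: identifiers, per-line lengths, the EOL style and
    the presence of a final newline together reproduce the input exactly.
    """
    if not input_bytes:
        raise EmptyInputError("empty input")
    lines, eol, final_newline = _split_lines(input_bytes)
    fmt = detect_format(input_bytes)

    records: list[SequenceRecord] = []
    if fmt == "raw":
        residues: list[str] = []
        lengths: list[int] = []
        for line in lines:
            _check_sequence_line(line)
            residues.append(line)
            lengths.append(len(line))
        records.append(SequenceRecord(None, "".join(residues), lengths))
    else:
        if not lines[0].startswith(">"):
            raise MalformedFastaError("content before the first '>' header")
        ident: str | None = None
        residues = []
        lengths = []
        for line in lines:
            if line.startswith(">"):
                if ident is not None:
                    if not residues:
                        raise MalformedFastaError(f"record {ident!r} has no sequence")
                    records.append(SequenceRecord(ident, "".join(residues), lengths))
                ident, residues, lengths = line, [], []
            else:
                _check_sequence_line(line)
                residues.append(line)
                lengths.append(len(line))
        if not residues:
            raise MalformedFastaError(f"record {ident!r} has no sequence")
        records.append(SequenceRecord(ident, "".join(residues), lengths))
    return ParsedInput(records, eol, final_newline, fmt)


def record_core_alphabet(residues_upper: str) -> tuple[str, bool]:
    """Core alphabet for one record and whether it is RNA-flagged.

    A record using U and no T is treated as RNA (U occupies the T slot);
    a record mixing T and U keeps the DNA alphabet and U becomes a special
    character, preserving losslessness.
    """
    if "U" in residues_upper and "T" not in residues_upper:
        return RNA_CORE, True
    return DNA_CORE, False


def extract_streams(
    records: list[SequenceRecord],
    eol: str = "lf",
    final_newline: bool = True,
) -> ExtractionResult:
    """Separate parsed records into the core stream and auxiliary streams.

    Case runs and special positions are recorded in full per-record
    coordinates (before special removal), then delta-coded. The core is the
    concatenation of the per-record residues, uppercased, with special
    characters removed.
    """
    aux = AuxiliaryStreams(eol=eol, final_newline=final_newline)
    core_parts: list[str] = []
    block_lengths: list[int] = []
    n_seq = 0
    n_spl = 0
    for rec in records:
        if rec.identifier is not None:
            aux.identifiers.append(rec.identifier)
        upper = rec.residues.upper()
        alphabet, rna = record_core_alphabet(upper)
        aux.rna_flags.append(rna)

        runs: list[tuple[int, int]] = []
        start = None
        for i, ch in enumerate(rec.residues):
            if ch.islower():
                if start is None:
                    start = i
            elif start is not None:
                runs.append((start, i - start))
                start = None
        if start is not None:
            runs.append((start, len(rec.residues) - start))
        aux.case_runs.append(encode_case_runs(runs))

        specials = [(i, ch) for i, ch in enumerate(upper) if ch not in alphabet]
        aux.specials.append(encode_specials(specials, core_alphabet=alphabet))

        core_parts.append("".join(ch for ch in upper if ch in alphabet))
        aux.line_length_rle.append(rle_line_lengths(rec.line_lengths))
        block_lengths.append(len(rec.residues))
        n_seq += len(rec.residues)
        n_spl += len(specials)
    aux.block_length_deltas = delta_block_lengths(block_lengths)
    return ExtractionResult("".join(core_parts), aux, n_seq, n_spl)


def record_core_lengths(aux: AuxiliaryStreams) -> list[int]:
    """Core-stream characters contributed by each record (block - specials)."""
    blocks = undelta_block_lengths(aux.block_length_deltas)
    out = []
    for i, block in enumerate(blocks):
        n_spl = len(aux.specials[i])
        if block - n_spl < 0:
            raise CorruptStreamError("more specials than residues in a record")
        out.append(block - n_spl)
    return out


def restore_records(core: str, aux: AuxiliaryStreams, fmt: str | None = None) -> bytes:
    """Rebuild the original input bytes from the core and auxiliary streams.

    Exact inverse of ``extract_streams . parse_input``: reinserts special
    characters at their absolute positions, reapplies lowercase runs,
    rewraps lines, restores identifiers and the original EOL convention.
    """
    blocks = undelta_block_lengths(aux.block_length_deltas)
    n_records = len(blocks)
    if not (
        len(aux.case_runs) == len(aux.specials) == len(aux.line_length_rle)
        == len(aux.rna_flags) == n_records
    ):
        raise CorruptStreamError("auxiliary stream record counts disagree")
    total_specials = sum(len(s) for s in aux.specials)
    if sum(blocks) != len(core) + total_specials:
        raise CorruptStreamError(
            "block lengths inconsistent with core length plus special count"
        )
    if fmt is None:
        fmt = "raw" if not aux.identifiers else (
            "multifasta" if len(aux.identifiers) > 1 else "fasta"
        )
    if fmt != "raw" and len(aux.identifiers) != n_records:
        raise CorruptStreamError("identifier count does not match record count")

    lines: list[str] = []
    cursor = 0
    for i in range(n_records):
        block = blocks[i]
        special_at = dict(decode_specials(aux.specials[i]))
        core_len = block - len(special_at)
        chunk = core[cursor : cursor + core_len]
        cursor += core_len

        chars: list[str] = []
        ci = 0
        for pos in range(block):
            sp = special_at.get(pos)
            if sp is not None:
                chars.append(sp)
            else:
                if ci >= len(chunk):
                    raise CorruptStreamError("core stream exhausted mid-record")
                chars.append(chunk[ci])
                ci += 1
        for start, length in decode_case_runs(aux.case_runs[i]):
            if start + length > block:
                raise CorruptStreamError("lowercase run exceeds record length")
            for j in range(start, start + length):
                chars[j] = chars[j].lower()
        residues = "".join(chars)

        if fmt != "raw":
            lines.append(aux.identifiers[i])
        offset = 0
        line_lengths = expand_line_lengths(aux.line_length_rle[i])
        if sum(line_lengths) != block:
            raise CorruptStreamError("line lengths do not cover the record")
        for length in line_lengths:
            lines.append(residues[offset : offset + length])
            offset += length
    if cursor != len(core):
        raise CorruptStreamError("core stream not fully consumed")

    text = "\n".join(lines)
    if aux.final_newline and lines:
        text += "\n"
    if aux.eol == "crlf":
        text = text.replace("\n", "\r\n")
    return text.encode("ascii")
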