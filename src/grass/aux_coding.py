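"""Serialization of the auxiliary (F2) metadata streams.

The auxiliary side-channel carries everything that is stripped from the
nucleotide stream during preprocessing: record identifiers, lowercase-run
coordinates, special-character entries, the per-record line layout and the
per-record block lengths. Each kind of value gets the encoding that suits
its statistics:

* lowercase runs and special characters — modified delta coding of
  positions (first entry absolute, later entries as gaps), so long files
  produce small numbers;
* line lengths — run-length encoding, since wrap widths are constant for
  long stretches;
* block lengths — delta coding with zig-zag mapping for negative
  differences;
* run lengths and special-character codes — static canonical Huffman
  coding with an explicit code-length table.

All integers on the wire are unsigned LEB128 varints. The serialized
payload is self-delimiting: decoding consumes exactly the bytes encoding
produced.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

from .errors import (
    CorruptStreamError,
    InvalidLayoutError,
    InvalidRunError,
    InvalidSpecialError,
)

# ---------------------------------------------------------------------------
# Stream element types
# ---------------------------------------------------------------------------


class CaseRun(NamedTuple):
    """Delta-coded lowercase run.

    ``gap`` is the absolute 0-based start for the first run of a record and
    the distance from the *end* of the previous run for later runs;
    ``length`` is the run length in residues.
    """

    gap: int
    length: int


class SpecialEntry(NamedTuple):
    """Delta-coded special character (a letter outside the core alphabet).

    ``gap`` is the absolute 0-based position for the first entry and the
    difference from the previous special's position for later entries;
    ``code`` is the letter index in the English alphabet ('A' -> 0).
    """

    gap: int
    code: int


class RlePair(NamedTuple):
    """One maximal run of equal line lengths: (value, repeat)."""

    value: int
    repeat: int


@dataclass
class AuxiliaryStreams:
    """The full F2 content for a parsed input.

    Per-record lists are parallel: entry ``i`` of ``case_runs``,
    ``specials``, ``line_length_rle`` and ``rna_flags`` all describe the
    ``i``-th record. ``eol`` and ``final_newline`` describe the whole file
    and are stored in the archive header, not in the serialized payload.
    """

    identifiers: list[str] = field(default_factory=list)
    case_runs: list[list[CaseRun]] = field(default_factory=list)
    specials: list[list[SpecialEntry]] = field(default_factory=list)
    line_length_rle: list[list[RlePair]] = field(default_factory=list)
    block_length_deltas: list[int] = field(default_factory=list)
    rna_flags: list[bool] = field(default_factory=list)
    eol: str = "lf"  # "lf" | "crlf"
    final_newline: bool = True

    @property
    def record_count(self) -> int:
        return len(self.block_length_deltas)


# ---------------------------------------------------------------------------
# Delta / RLE primitives
# ---------------------------------------------------------------------------


def encode_case_runs(absolute_runs: Sequence[tuple[int, int]]) -> list[CaseRun]:
    """Delta-code absolute lowercase runs (start, length).

    The first tuple keeps its absolute start; every later tuple stores the
    gap from the end of the previous run, so ``(9,6),(19,3),(29,7)`` becomes
    ``(9,6),(4,3),(7,7)``.
    """
    out: list[CaseRun] = []
    prev_end = 0
    for start, length in absolute_runs:
        if length < 1:
            raise InvalidRunError(f"non-positive run length {length}")
        if start < prev_end:
            raise InvalidRunError(
                f"run at {start} overlaps or precedes previous run ending at {prev_end}"
            )
        out.append(CaseRun(start - prev_end, length))
        prev_end = start + length
    return out


def decode_case_runs(runs: Iterable[CaseRun]) -> list[tuple[int, int]]:
    """Inverse of :func:`encode_case_runs`: recover absolute (start, length)."""
    out: list[tuple[int, int]] = []
    prev_end = 0
    for gap, length in runs:
        if gap < 0 or length < 1:
            raise InvalidRunError(f"invalid delta-coded run ({gap}, {length})")
        start = prev_end + gap
        out.append((start, length))
        prev_end = start + length
    return out


def encode_specials(
    absolute_entries: Sequence[tuple[int, str]],
    core_alphabet: str | None = None,
) -> list[SpecialEntry]:
    """Delta-code (position, letter) special entries.

    First entry keeps its absolute position; later entries store the
    difference from the previous position. Letters map to their 0-based
    alphabet index ('Y' -> 24).
    """
    out: list[SpecialEntry] = []
    prev = None
    for pos, letter in absolute_entries:
        if not ("A" <= letter <= "Z"):
            raise InvalidSpecialError(f"special character {letter!r} is not A-Z")
        if core_alphabet is not None and letter in core_alphabet:
            raise InvalidSpecialError(
                f"{letter!r} belongs to the core alphabet {core_alphabet}"
            )
        if prev is None:
            out.append(SpecialEntry(pos, ord(letter) - 65))
        else:
            if pos <= prev:
                raise InvalidSpecialError("special positions must be strictly increasing")
            out.append(SpecialEntry(pos - prev, ord(letter) - 65))
        prev = pos
    return out


def decode_specials(entries: Iterable[SpecialEntry]) -> list[tuple[int, str]]:
    """Inverse of :func:`encode_specials`."""
    out: list[tuple[int, str]] = []
    pos = 0
    first = True
    for gap, code in entries:
        if not 0 <= code <= 25:
            raise CorruptStreamError(f"special code {code} outside 0..25")
        pos = gap if first else pos + gap
        first = False
        out.append((pos, chr(code + 65)))
    return out


def rle_line_lengths(lengths: Sequence[int]) -> list[RlePair]:
    """Maximal-run RLE of the per-line lengths of one record."""
    out: list[RlePair] = []
    for value in lengths:
        if value < 1:
            raise InvalidLayoutError(f"non-positive line length {value}")
        if out and out[-1].value == value:
            out[-1] = RlePair(value, out[-1].repeat + 1)
        else:
            out.append(RlePair(value, 1))
    return out


def expand_line_lengths(pairs: Iterable[RlePair]) -> list[int]:
    """Inverse of :func:`rle_line_lengths`."""
    out: list[int] = []
    for value, repeat in pairs:
        if value < 1 or repeat < 1:
            raise CorruptStreamError(f"invalid RLE pair ({value}, {repeat})")
        out.extend([value] * repeat)
    return out


def delta_block_lengths(lengths: Sequence[int]) -> list[int]:
    """Delta-code block lengths: first absolute, then successive differences."""
    out: list[int] = []
    prev = 0
    for i, value in enumerate(lengths):
        out.append(value if i == 0 else value - prev)
        prev = value
    return out


def undelta_block_lengths(deltas: Sequence[int]) -> list[int]:
    """Inverse of :func:`delta_block_lengths`."""
    out: list[int] = []
    prev = 0
    for i, d in enumerate(deltas):
        prev = d if i == 0 else prev + d
        out.append(prev)
    return out


# ---------------------------------------------------------------------------
# Varint / zig-zag primitives
# ---------------------------------------------------------------------------


def zigzag(n: int) -> int:
    return (n << 1) ^ (n >> 63) if n < 0 else n << 1


def unzigzag(n: int) -> int:
    return (n >> 1) ^ -(n & 1)


def write_uvarint(buf: bytearray, n: int) -> None:
    if n < 0:
        raise ValueError("uvarint cannot encode negatives")
    while True:
        b = n & 0x7F
        n >>= 7
        if n:
            buf.append(b | 0x80)
        else:
            buf.append(b)
            return


def read_uvarint(data: bytes, offset: int) -> tuple[int, int]:
    result = 0
    shift = 0
    while True:
        if offset >= len(data):
            raise CorruptStreamError("truncated varint")
        b = data[offset]
        offset += 1
        result |= (b & 0x7F) << shift
        if not b & 0x80:
            return result, offset
        shift += 7
        if shift > 70:
            raise CorruptStreamError("varint too long")


# ---------------------------------------------------------------------------
# Static entropy coder (canonical Huffman)
# ---------------------------------------------------------------------------


def _huffman_code_lengths(counts: dict[int, int]) -> dict[int, int]:
    """Code length per symbol for a Huffman tree over ``counts``.

    Deterministic: ties in the heap break on the smallest symbol of each
    subtree. A single distinct symbol gets length 0 (count-only coding).
    """
    if len(counts) <= 1:
        return {sym: 0 for sym in counts}
    # heap items: (weight, min_symbol, {symbol: depth})
    heap: list[tuple[int, int, dict[int, int]]] = [
        (w, s, {s: 0}) for s, w in counts.items()
    ]
    heapq.heapify(heap)
    while len(heap) > 1:
        w1, s1, d1 = heapq.heappop(heap)
        w2, s2, d2 = heapq.heappop(heap)
        merged = {s: d + 1 for s, d in d1.items()}
        merged.update({s: d + 1 for s, d in d2.items()})
        heapq.heappush(heap, (w1 + w2, min(s1, s2), merged))
    return heap[0][2]


def _canonical_codes(lengths: dict[int, int]) -> dict[int, tuple[int, int]]:
    """Assign canonical codes (code, length) from code lengths."""
    codes: dict[int, tuple[int, int]] = {}
    code = 0
    prev_len = 0
    for sym in sorted(lengths, key=lambda s: (lengths[s], s)):
        length = lengths[sym]
        code <<= length - prev_len
        codes[sym] = (code, length)
        code += 1
        prev_len = length
    return codes


def entropy_encode_values(values: Sequence[int]) -> bytes:
    """Encode non-negative integers with a static canonical Huffman code.

    The payload is self-describing: value count, symbol table with code
    lengths, then the MSB-first bitstream. Empty and single-symbol inputs
    degenerate to a count-only header.
    """
    buf = bytearray()
    write_uvarint(buf, len(values))
    if not values:
        return bytes(buf)
    counts: dict[int, int] = {}
    for v in values:
        if v < 0:
            raise ValueError("entropy coder takes non-negative values")
        counts[v] = counts.get(v, 0) + 1
    lengths = _huffman_code_lengths(counts)
    write_uvarint(buf, len(lengths))
    for sym in sorted(lengths):
        write_uvarint(buf, sym)
        write_uvarint(buf, lengths[sym])
    codes = _canonical_codes(lengths)
    acc = 0
    nbits = 0
    for v in values:
        code, length = codes[v]
        acc = (acc << length) | code
        nbits += length
        while nbits >= 8:
            nbits -= 8
            buf.append((acc >> nbits) & 0xFF)
    if nbits:
        buf.append((acc << (8 - nbits)) & 0xFF)
    return bytes(buf)


def entropy_decode_values(data: bytes, offset: int = 0) -> tuple[list[int], int]:
    """Inverse of :func:`entropy_encode_values`.

    Returns the decoded list and the offset one past the consumed bytes.
    """
    n, offset = read_uvarint(data, offset)
    if n == 0:
        return [], offset
    n_sym, offset = read_uvarint(data, offset)
    if n_sym == 0:
        raise CorruptStreamError("entropy header with values but no symbols")
    lengths: dict[int, int] = {}
    for _ in range(n_sym):
        sym, offset = read_uvarint(data, offset)
        length, offset = read_uvarint(data, offset)
        lengths[sym] = length
    if n_sym == 1:
        (sym,) = lengths
        if lengths[sym] != 0:
            raise CorruptStreamError("single-symbol table must have length 0")
        return [sym] * n, offset
    codes = _canonical_codes(lengths)
    # decoding table: (length, code) -> symbol
    by_code = {(ln, code): sym for sym, (code, ln) in codes.items()}
    max_len = max(ln for _, ln in codes.values())
    out: list[int] = []
    acc = 0
    nbits = 0
    pos = offset
    cur_len = 0
    cur_code = 0
    while len(out) < n:
        if nbits == 0:
            if pos >= len(data):
                raise CorruptStreamError("truncated entropy payload")
            acc = data[pos]
            pos += 1
            nbits = 8
        nbits -= 1
        cur_code = (cur_code << 1) | ((acc >> nbits) & 1)
        cur_len += 1
        if cur_len > max_len:
            raise CorruptStreamError("invalid entropy codeword")
        sym = by_code.get((cur_len, cur_code))
        if sym is not None:
            out.append(sym)
            cur_len = 0
            cur_code = 0
    return out, pos


# ---------------------------------------------------------------------------
# Auxiliary payload serialization
# ---------------------------------------------------------------------------

_SECTION_ORDER = ("identifiers", "case_runs", "specials", "line_rle", "block_deltas", "flags")


def _write_section(buf: bytearray, payload: bytes) -> None:
    write_uvarint(buf, len(payload))
    buf.extend(payload)


def _read_section(data: bytes, offset: int) -> tuple[bytes, int]:
    length, offset = read_uvarint(data, offset)
    if offset + length > len(data):
        raise CorruptStreamError("truncated auxiliary section")
    return data[offset : offset + length], offset + length


def serialize_aux(aux: AuxiliaryStreams) -> bytes:
    """Serialize the auxiliary streams into the length-prefixed section layout.

    Section order: identifiers, case runs, specials, line RLE, block deltas,
    flags. Gaps and positions are varints; run lengths and special codes are
    entropy-coded with separate per-section models.
    """
    buf = bytearray()

    sec = bytearray()
    write_uvarint(sec, len(aux.identifiers))
    for ident in aux.identifiers:
        raw = ident.encode("ascii")
        write_uvarint(sec, len(raw))
        sec.extend(raw)
    _write_section(buf, bytes(sec))

    sec = bytearray()
    write_uvarint(sec, len(aux.case_runs))
    all_lengths: list[int] = []
    for runs in aux.case_runs:
        write_uvarint(sec, len(runs))
        for run in runs:
            write_uvarint(sec, run.gap)
            all_lengths.append(run.length)
    sec.extend(entropy_encode_values(all_lengths))
    _write_section(buf, bytes(sec))

    sec = bytearray()
    write_uvarint(sec, len(aux.specials))
    all_codes: list[int] = []
    for entries in aux.specials:
        write_uvarint(sec, len(entries))
        for entry in entries:
            write_uvarint(sec, entry.gap)
            all_codes.append(entry.code)
    sec.extend(entropy_encode_values(all_codes))
    _write_section(buf, bytes(sec))

    sec = bytearray()
    write_uvarint(sec, len(aux.line_length_rle))
    for pairs in aux.line_length_rle:
        write_uvarint(sec, len(pairs))
        for value, repeat in pairs:
            write_uvarint(sec, value)
            write_uvarint(sec, repeat)
    _write_section(buf, bytes(sec))

    sec = bytearray()
    write_uvarint(sec, len(aux.block_length_deltas))
    for d in aux.block_length_deltas:
        write_uvarint(sec, zigzag(d))
    _write_section(buf, bytes(sec))

    sec = bytearray()
    write_uvarint(sec, len(aux.rna_flags))
    bits = 0
    for i, flag in enumerate(aux.rna_flags):
        if flag:
            bits |= 1 << (i & 7)
        if i & 7 == 7:
            sec.append(bits)
            bits = 0
    if len(aux.rna_flags) & 7:
        sec.append(bits)
    _write_section(buf, bytes(sec))

    return bytes(buf)


def deserialize_aux(data: bytes) -> AuxiliaryStreams:
    """Exact inverse of :func:`serialize_aux`.

    Raises :class:`CorruptStreamError` on truncation or trailing bytes.
    ``eol``/``final_newline`` are left at their defaults; the archive reader
    fills them from the header.
    """
    aux = AuxiliaryStreams()
    offset = 0

    sec, offset = _read_section(data, offset)
    pos = 0
    n, pos = read_uvarint(sec, pos)
    for _ in range(n):
        length, pos = read_uvarint(sec, pos)
        if pos + length > len(sec):
            raise CorruptStreamError("truncated identifier")
        aux.identifiers.append(sec[pos : pos + length].decode("ascii"))
        pos += length

    sec, offset = _read_section(data, offset)
    pos = 0
    n, pos = read_uvarint(sec, pos)
    gaps_per_record: list[list[int]] = []
    for _ in range(n):
        k, pos = read_uvarint(sec, pos)
        gaps: list[int] = []
        for _ in range(k):
            g, pos = read_uvarint(sec, pos)
            gaps.append(g)
        gaps_per_record.append(gaps)
    lengths, pos = entropy_decode_values(sec, pos)
    it = iter(lengths)
    for gaps in gaps_per_record:
        aux.case_runs.append([CaseRun(g, next(it)) for g in gaps])
    if sum(len(g) for g in gaps_per_record) != len(lengths):
        raise CorruptStreamError("case-run length count mismatch")

    sec, offset = _read_section(data, offset)
    pos = 0
    n, pos = read_uvarint(sec, pos)
    sgaps_per_record: list[list[int]] = []
    for _ in range(n):
        k, pos = read_uvarint(sec, pos)
        gaps = []
        for _ in range(k):
            g, pos = read_uvarint(sec, pos)
            gaps.append(g)
        sgaps_per_record.append(gaps)
    codes, pos = entropy_decode_values(sec, pos)
    if sum(len(g) for g in sgaps_per_record) != len(codes):
        raise CorruptStreamError("special code count mismatch")
    it = iter(codes)
    for gaps in sgaps_per_record:
        aux.specials.append([SpecialEntry(g, next(it)) for g in gaps])

    sec, offset = _read_section(data, offset)
    pos = 0
    n, pos = read_uvarint(sec, pos)
    for _ in range(n):
        k, pos = read_uvarint(sec, pos)
        pairs: list[RlePair] = []
        for _ in range(k):
            v, pos = read_uvarint(sec, pos)
            r, pos = read_uvarint(sec, pos)
            pairs.append(RlePair(v, r))
        aux.line_length_rle.append(pairs)

    sec, offset = _read_section(data, offset)
    pos = 0
    n, pos = read_uvarint(sec, pos)
    for _ in range(n):
        z, pos = read_uvarint(sec, pos)
        aux.block_length_deltas.append(unzigzag(z))

    sec, offset = _read_section(data, offset)
    pos = 0
    n, pos = read_uvarint(sec, pos)
    nbytes = (n + 7) // 8
    if pos + nbytes > len(sec):
        raise CorruptStreamError("truncated flag bitset")
    for i in range(n):
        aux.rna_flags.append(bool(sec[pos + (i >> 3)] >> (i & 7) & 1))

    if offset != len(data):
        raise CorruptStreamError("trailing bytes after auxiliary payload")
    return aux
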