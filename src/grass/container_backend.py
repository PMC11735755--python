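"""Archive container and the pluggable general-purpose backend codec.

The final stage hands two payloads — the serialized auxiliary streams and
the nine-symbol pair stream — to a parameter-free general-purpose
compressor. The backend is a contract (bytes -> bytes, lossless, no
tunables); the default is the stdlib BWT-family block compressor (bz2),
with a dictionary-based alternate (zlib). The archive header carries
everything the decoder cannot re-derive: the symbol ranking, the odd
trailing digit, layout flags and a CRC-32 of the original input.

The byte-exact header layout is documented in docs/FORMAT.md.
"""

from __future__ import annotations

import bz2
import itertools
import struct
import zlib
from dataclasses import dataclass
from typing import Callable

from . import core_codec, sequence_io
from .aux_coding import (
    AuxiliaryStreams,
    deserialize_aux,
    read_uvarint,
    serialize_aux,
    write_uvarint,
)
from .core_codec import CORE_SYMBOLS, SymbolRanking
from .errors import (
    ConfigurationError,
    CorruptArchiveError,
    NotAGrassArchiveError,
    UnsupportedVersionError,
)

__all__ = [
    "MAGIC",
    "VERSION",
    "BACKENDS",
    "DEFAULT_BACKEND",
    "BackendCodec",
    "GrassArchive",
    "backend_compress",
    "backend_decompress",
    "write_archive",
    "read_archive",
    "compress",
    "decompress",
]

MAGIC = b"GrSS"
VERSION = 1

_FORMAT_TAGS = ("raw", "fasta", "multifasta")
# All 120 orderings of the core symbols; the header stores an index.
_PERMUTATIONS = ["".join(p) for p in itertools.permutations(CORE_SYMBOLS)]


@dataclass(frozen=True)
class BackendCodec:
    """A parameter-free lossless bytes -> bytes codec."""

    identifier: int
    name: str
    compress: "Callable[[bytes], bytes]"
    decompress: "Callable[[bytes], bytes]"


BACKENDS: dict[int, BackendCodec] = {
    0: BackendCodec(0, "bz2", lambda b: bz2.compress(b, 9), bz2.decompress),
    1: BackendCodec(1, "zlib", lambda b: zlib.compress(b, 9), zlib.decompress),
}
DEFAULT_BACKEND = 0
BACKEND_NAMES = {c.name: i for i, c in BACKENDS.items()}


def backend_compress(data: bytes, backend_id: int = DEFAULT_BACKEND) -> bytes:
    codec = BACKENDS.get(backend_id)
    if codec is None:
        raise ConfigurationError(f"unknown backend id {backend_id}")
    return codec.compress(data)


def backend_decompress(data: bytes, backend_id: int = DEFAULT_BACKEND) -> bytes:
    codec = BACKENDS.get(backend_id)
    if codec is None:
        raise ConfigurationError(f"unknown backend id {backend_id}")
    try:
        return codec.decompress(data)
    except Exception as exc:  # backend-specific error types
        raise CorruptArchiveError(f"backend payload failed to decompress: {exc}") from None


@dataclass
class GrassArchive:
    """Decoded archive: header fields plus decompressed payloads."""

    backend_id: int
    ranking: SymbolRanking
    trailing_digit: str | None
    eol: str
    final_newline: bool
    format_tag: str
    crc32: int
    aux: AuxiliaryStreams
    pairs: str


def _ranking_to_byte(ranking: SymbolRanking) -> int:
    return _PERMUTATIONS.index("".join(ranking))


def _ranking_from_byte(b: int) -> SymbolRanking:
    if not 0 <= b < len(_PERMUTATIONS):
        raise CorruptArchiveError(f"invalid ranking byte {b}")
    return SymbolRanking(*_PERMUTATIONS[b])


def write_archive(
    aux: AuxiliaryStreams,
    pairs: str,
    ranking: SymbolRanking,
    trailing_digit: str | None,
    format_tag: str,
    crc32: int,
    backend_id: int = DEFAULT_BACKEND,
) -> bytes:
    """Assemble a self-delimiting archive; all header fields round-trip."""
    if format_tag not in _FORMAT_TAGS:
        raise ConfigurationError(f"unknown format tag {format_tag!r}")
    if backend_id not in BACKENDS:
        raise ConfigurationError(f"unknown backend id {backend_id}")
    buf = bytearray()
    buf += MAGIC
    buf.append(VERSION)
    buf.append(backend_id)
    buf.append(_ranking_to_byte(ranking))
    buf.append(0xFF if trailing_digit is None else int(trailing_digit))
    flags = (1 if aux.eol == "crlf" else 0) | (2 if aux.final_newline else 0)
    flags |= _FORMAT_TAGS.index(format_tag) << 2
    buf.append(flags)
    buf += struct.pack(">I", crc32 & 0xFFFFFFFF)
    aux_payload = backend_compress(serialize_aux(aux), backend_id)
    pair_payload = backend_compress(pairs.encode("ascii"), backend_id)
    write_uvarint(buf, len(aux_payload))
    buf += aux_payload
    write_uvarint(buf, len(pair_payload))
    buf += pair_payload
    return bytes(buf)


def read_archive(data: bytes) -> GrassArchive:
    """Parse and validate an archive; exact inverse of :func:`write_archive`."""
    if len(data) < 4 or data[:4] != MAGIC:
        raise NotAGrassArchiveError("missing grass archive magic")
    if len(data) < 14:
        raise CorruptArchiveError("truncated archive header")
    version = data[4]
    if version > VERSION:
        raise UnsupportedVersionError(
            f"archive version {version} is newer than supported version {VERSION}"
        )
    backend_id = data[5]
    if backend_id not in BACKENDS:
        raise ConfigurationError(f"unknown backend id {backend_id}")
    ranking = _ranking_from_byte(data[6])
    tbyte = data[7]
    if tbyte == 0xFF:
        trailing: str | None = None
    elif tbyte in (0, 1, 2):
        trailing = str(tbyte)
    else:
        raise CorruptArchiveError(f"invalid trailing-digit byte {tbyte}")
    flags = data[8]
    eol = "crlf" if flags & 1 else "lf"
    final_newline = bool(flags & 2)
    fmt_idx = (flags >> 2) & 0x3
    if fmt_idx >= len(_FORMAT_TAGS):
        raise CorruptArchiveError(f"invalid format tag {fmt_idx}")
    format_tag = _FORMAT_TAGS[fmt_idx]
    (crc,) = struct.unpack(">I", data[9:13])
    offset = 13
    n, offset = read_uvarint(data, offset)
    if offset + n > len(data):
        raise CorruptArchiveError("truncated auxiliary payload")
    aux_payload = data[offset : offset + n]
    offset += n
    n, offset = read_uvarint(data, offset)
    if offset + n > len(data):
        raise CorruptArchiveError("truncated pair payload")
    pair_payload = data[offset : offset + n]
    offset += n
    if offset != len(data):
        raise CorruptArchiveError("trailing bytes after archive payloads")
    aux = deserialize_aux(backend_decompress(aux_payload, backend_id))
    aux.eol = eol
    aux.final_newline = final_newline
    try:
        pairs = backend_decompress(pair_payload, backend_id).decode("ascii")
    except UnicodeDecodeError:
        raise CorruptArchiveError("pair payload is not ASCII") from None
    return GrassArchive(
        backend_id, ranking, trailing, eol, final_newline, format_tag, crc, aux, pairs
    )


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


def compress(
    data: bytes,
    backend_id: int = DEFAULT_BACKEND,
    timings: dict[str, float] | None = None,
) -> bytes:
    """Compress raw/FASTA/multi-FASTA bytes into a grass archive.

    An empty input maps to a minimal zero-record archive so that the
    round trip is total. ``timings``, when given, is filled with per-stage
    wall-clock seconds.
    """
    import time

    def tick(stage: str, t0: float) -> float:
        t1 = time.perf_counter()
        if timings is not None:
            timings[stage] = timings.get(stage, 0.0) + (t1 - t0)
        return t1

    t0 = time.perf_counter()
    if data == b"":
        aux = AuxiliaryStreams(final_newline=False)
        ranking = core_codec.rank_symbols(core_codec.count_frequencies(""))
        return write_archive(aux, "", ranking, None, "raw", zlib.crc32(data), backend_id)
    parsed = sequence_io.parse_input(data)
    t0 = tick("parse", t0)
    extraction = sequence_io.extract_streams(
        parsed.records, eol=parsed.eol, final_newline=parsed.final_newline
    )
    t0 = tick("extract", t0)
    # RNA records keep U in the visible core; Phase 2 works in the T slot.
    core = extraction.core.replace("U", "T")
    pairs, trailing, ranking = core_codec.encode_core(core)
    t0 = tick("grammar", t0)
    archive = write_archive(
        extraction.aux, pairs, ranking, trailing, parsed.format,
        zlib.crc32(data), backend_id,
    )
    tick("backend", t0)
    return archive


def decompress(archive: bytes, timings: dict[str, float] | None = None) -> bytes:
    """Exact inverse of :func:`compress`; verifies the stored checksum."""
    import time

    t0 = time.perf_counter()
    arc = read_archive(archive)
    if timings is not None:
        timings["backend"] = time.perf_counter() - t0
    t0 = time.perf_counter()
    core = core_codec.decode_core(arc.pairs, arc.trailing_digit, arc.ranking)
    if timings is not None:
        timings["grammar"] = time.perf_counter() - t0
    t0 = time.perf_counter()
    if any(arc.aux.rna_flags):
        # map the T slot back to U inside RNA-flagged record spans
        lengths = sequence_io.record_core_lengths(arc.aux)
        parts = []
        pos = 0
        for length, rna in zip(lengths, arc.aux.rna_flags):
            chunk = core[pos : pos + length]
            parts.append(chunk.replace("T", "U") if rna else chunk)
            pos += length
        core = "".join(parts)
    data = sequence_io.restore_records(core, arc.aux, arc.format_tag)
    if timings is not None:
        timings["restore"] = time.perf_counter() - t0
    if zlib.crc32(data) != arc.crc32:
        raise CorruptArchiveError("checksum mismatch after decompression")
    return data
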