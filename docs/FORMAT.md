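# `.grass` archive format, version 1

All multi-byte integers are unsigned LEB128 varints unless stated
otherwise. The archive is self-delimiting; trailing bytes are an error.

## Header (13 bytes, fixed)

| offset | size | field |
|---|---|---|
| 0 | 4 | magic `47 72 53 53` (`GrSS`) |
| 4 | 1 | version (1) |
| 5 | 1 | backend id: 0 = bz2 (default), 1 = zlib |
| 6 | 1 | symbol ranking: index into the lexicographic permutations of `ACGTN`, ordered (least, 2nd-least, 3rd-least, HFS, 2nd-HFS) |
| 7 | 1 | trailing digit: `0x00`/`0x01`/`0x02`, or `0xFF` = none |
| 8 | 1 | flags: bit 0 = CRLF line endings; bit 1 = file ends with a newline; bits 2–3 = format (0 raw, 1 fasta, 2 multifasta) |
| 9 | 4 | CRC-32 of the original input, big-endian |

## Payloads

Two length-prefixed, backend-compressed blobs follow the header:

1. `varint len` + auxiliary payload (the serialized F2 streams, below)
2. `varint len` + pair payload (the nine-symbol pair stream, ASCII)

## Auxiliary payload sections

Six length-prefixed sections, in order. Every section starts with its
byte length as a varint, then:

1. **identifiers** — count; per identifier: byte length + ASCII bytes
   (verbatim header line including `>`).
2. **case runs** — record count; per record: run count, then that
   record's gaps (varints); then one entropy blob of *all* run lengths in
   order.
3. **specials** — record count; per record: entry count, then gaps
   (varints); then one entropy blob of all letter codes (`'A'`→0).
4. **line RLE** — record count; per record: pair count, then
   (value, repeat) varint pairs.
5. **block deltas** — count; zig-zag varints (first absolute, then
   successive differences).
6. **flags** — record count; RNA flags as a little-endian bitset,
   one bit per record.

## Entropy blob

`varint n` (value count); if n > 0: `varint k` (distinct symbols), then k
× (`varint symbol`, `varint code length`) sorted by symbol, then the
canonical-Huffman bitstream MSB-first, zero-padded to a byte boundary.
Codes are canonical over (length, symbol); a single distinct symbol has
code length 0 and an empty bitstream.
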