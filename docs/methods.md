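# Methods

## Model and assumptions

`grass` is a reference-free, lossless codec for nucleotide text. It
assumes ASCII input in one of three layouts — raw single-sequence text,
FASTA (one `>` header) or multi-FASTA — whose residues are letters:
the five core symbols A, C, G, T (or U), N in either case, plus any other
letter treated as a "special" character (this covers the IUPAC ambiguity
codes R, Y, S, W, K, M, B, D, H, V). It makes no assumption about repeat
structure: unlike repeat- or context-model compressors, the grammar stage
exploits only the global symbol frequencies, which is what makes the
method fast and memory-light, and also what bounds its ratio on highly
repetitive data.

### Phase 1 — stream separation

Per record the parser captures the verbatim header, the residue string and
the length of every sequence line. Extraction then records, in 0-based
coordinates over the *full* residue string (before any removal):

* lowercase runs as (start, length), delta-coded so that the first tuple
  keeps its absolute start and each later tuple stores the gap from the
  **end** of the previous run — runs at 9, 19, 29 with lengths 6, 3, 7
  encode as (9, 6), (4, 3), (7, 7);
* special characters as (position, letter-index 'A'→0), first position
  absolute, later ones differenced from the previous special;
* line lengths as maximal-run RLE pairs; block (record) lengths as
  first-absolute deltas, zig-zag mapped because a later record may be
  shorter.

The identity `n_tar = n_seq − n_spl` (core = residues − specials) is
asserted throughout the test suite.

**U/T policy.** A record containing U and no T is flagged RNA: U occupies
the T slot of the five-symbol alphabet end-to-end and is restored on
decode from the per-record flag. A record mixing T and U keeps the DNA
alphabet and its Us become special characters. This keeps a single
5-letter core alphabet while remaining lossless on any mixture of DNA and
RNA records in one file.

**Line endings.** Lines are normalised to LF internally; one archive-level
flag restores CRLF, another the missing final newline. Files mixing LF and
CRLF cannot be represented by a single flag and are rejected rather than
silently normalised — the codec's contract is byte identity or an error.
Records with no sequence line, and blank lines inside a record, are
likewise rejected (they would violate the positive block/line-length
invariants of the stream model).

### Phase 2 — grammar reduction

Frequencies of the five core symbols are tallied over the concatenated
core stream (U mapped into the T slot). Ranking is ascending by count with
a fixed deterministic tie rule: on equal counts the later symbol in the
order A < C < G < T < N is deemed *less* frequent. The ranking is stored
in the archive header (one byte, index into the 120 permutations), so the
decoder never re-derives it and the tie rule can never cause a mismatch.

Rule 1 maps least → `ZZ`, second-least → `Z`+HFS, third-least →
`Z`+second-HFS. The resulting code over {HFS, second-HFS, Z} is a prefix
code (a non-Z symbol is always a 1-codeword, Z always opens a
2-codeword), hence uniquely decodable; the suite verifies this
exhaustively against the parse-count recurrence for every 3-symbol string
up to length 12. The substitution HFS→0, second-HFS→1, Z→2 and the fixed
nine-entry pair table then halve the stream. The pair alphabet
P,Q,R,S,U,V,W,X,Y deliberately skips T so no pair symbol collides with a
nucleotide letter. An odd trailing digit is carried in the header rather
than padded, so the expanded length `ñ_tar = 2(l+s_l+t_l)+o_l` is exactly
recoverable. Degenerate cores (empty, single-symbol, missing symbols) are
handled by the same path: zero-count symbols are still ranked by the tie
rule and simply never occur.

### Serialization and container

Integers on the wire are unsigned LEB128 varints. Lowercase-run lengths
and special-character codes are entropy-coded with a static canonical
Huffman code whose code-length table is serialized in the section header;
empty and single-symbol inputs degenerate to count-only headers. Each kind
of value gets its own model (lengths and codes are not pooled — their
distributions differ and the cost is a few header bytes). "Static" was
chosen over adaptive/arithmetic coding for determinism and because the
general-purpose backend mops up residual redundancy anyway.

The archive (see `FORMAT.md`) stores magic, version, backend id, the
ranking byte, the trailing digit, layout flags, a CRC-32 of the original
input and two independently backend-compressed payloads (auxiliary
streams; pair stream). Compressing the two payloads separately keeps the
contracts clean at the cost of a few bytes versus one concatenated
stream. The CRC is verified after full reconstruction, so corruption
fails loudly instead of yielding a plausible but wrong file.

### Backend

The final stage is a pluggable parameter-free bytes→bytes codec:
id 0 = bz2 (BWT block-sorting family, the default), id 1 = zlib
(dictionary/LZ77 family). Both are deterministic at fixed level 9, so
identical input always yields an identical archive. Absolute compressed
sizes depend on this choice; losslessness and the transform behaviour do
not, and only the latter are claimed.

## Tunable parameters

| Parameter | Default | Meaning |
|---|---|---|
| `backend` | `bz2` (id 0) | final-stage general-purpose codec; `zlib` trades ratio for speed |
| `GeneratorParams.record_count` | 3 | records per synthetic file |
| `GeneratorParams.length_range` | (500, 2000) bp | per-record length, uniform |
| `GeneratorParams.base_weights` | (.25, .25, .25, .25) | A/C/G/T(U) composition |
| `GeneratorParams.n_rate` | 0.01 | per-base probability of N |
| `GeneratorParams.special_rate` | 0.002 | per-base probability of an ambiguity code |
| `GeneratorParams.lowercase_rate` | 0.005 | per-base probability a soft-mask run starts |
| `GeneratorParams.lowercase_mean_length` | 20 bp | geometric mean run length |
| `GeneratorParams.wrap` | 60 | FASTA line width |

The codec itself is parameter-free apart from the backend choice — that
is the point of the design.

## What the synthetic generator does and does not emulate

The generator (seeded Mersenne Twister via `random.Random`, so output is
reproducible across platforms) emulates the *structural* features the
codec must preserve: mixed-case soft masking with geometric run lengths,
sparse ambiguity codes, N runs, arbitrary wrap widths, DNA/RNA alphabets,
one-to-many records, LF/CRLF. It draws bases i.i.d., so it does **not**
emulate the repeat structure, GC skew, isochores or homopolymer runs of
real genomes. Passing the round-trip suite therefore demonstrates
losslessness over the format space; the compression *ratios* measured on
synthetic data (≈3.4 on i.i.d. uniform bases, near the 2-bit entropy
floor plus backend overhead) say little about ratios on real, repetitive
genomes.

## Numerical and edge-case choices

* Coordinates are 0-based over the pre-removal residue string; the first
  delta of each positional stream is absolute.
* Negative block-length deltas are zig-zag mapped before varint coding.
* Empty input compresses to a minimal zero-record archive (the parser by
  itself rejects empty files; the pipeline makes the round trip total).
* Huffman ties break on (code length, symbol value) — canonical codes —
  and the tree merge breaks ties on the smallest contained symbol, so
  encoding is platform-independent.
* All-special records yield an empty core chunk; the restore path
  reinserts every character from the auxiliary stream alone.

## Problem sizes used in the checks

The round-trip acceptance battery runs 216 generated files of 1–3 records
at 30–400 bp across the full format grid plus degenerate inputs; the
per-stage inverse identity runs 10,000 random cores up to 40 symbols
(including subset-alphabet degenerates); one end-to-end case uses a
~300 kb five-record multi-FASTA. These sizes exercise every code path
while keeping the default suite fast; the codec itself is linear-time and
has been run on megabyte-scale inputs in the backend tests.

## Known limitations

* No random access into archives and no streaming decompression; a file
  is (de)compressed as a whole, with memory proportional to input size.
* Non-letter residue bytes (digits, `*`, `-` gaps) are rejected, not
  escaped; protein FASTA and FASTQ are out of scope.
* Mixed LF/CRLF files are rejected (see above).
* Compression of very small files is poor — the fixed header plus two
  backend streams dominate below a few hundred bytes.
* The frequency model is global across all records; a file whose records
  have wildly different compositions gets one shared ranking.
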