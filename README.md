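# grass — reference-free lossless compression of nucleotide files

`grass` compresses raw, FASTA and multi-FASTA DNA/RNA text files without a
reference genome and restores them **byte-for-byte** — headers, line
wrapping, soft-masked lowercase, IUPAC ambiguity codes, CRLF/LF style and
all. It is aimed at people who archive and ship sequence downloads
(GenBank-style FASTA, rRNA databases, raw sequence corpora) and need a
compressor whose output is provably reversible rather than merely
"the right size".

## The method

Compression runs in two phases.

**Phase 1 — stream separation.** The file is split into a core nucleotide
stream F1 over the five symbols {A, C, G, T/U, N} and auxiliary streams F2
holding everything else: identifiers (verbatim), lowercase runs as
delta-coded *(position, length)* tuples, special characters (any letter
outside the core alphabet, e.g. the ambiguity codes R, Y, W…) as
delta-coded *(position, letter-index)* tuples, line lengths as run-length
pairs and per-record block lengths as deltas. With `n_seq` residues of
which `n_spl` are special, the core carries

```
n_tar = n_seq − n_spl
```

characters. Run lengths and special codes are entropy-coded with a static
canonical Huffman code; positions use varint delta coding.

**Phase 2 — grammar reduction.** The five core symbols are tallied; let
`l ≤ s_l ≤ t_l` be the three smallest counts, `o_l` the sum of the two
largest, and call the two most frequent symbols HFS and second-HFS.
Grammar rule 1 rewrites the three rare symbols as two-character codewords
behind a flag symbol Z:

```
least → ZZ     second-least → Z·HFS     third-least → Z·second-HFS
```

leaving a three-symbol stream of length `ñ_tar = 2(l + s_l + t_l) + o_l`.
The substitution rule relabels HFS→0, second-HFS→1, Z→2, and grammar
rule 2 folds adjacent digit pairs through a fixed nine-symbol table
(00→P, 01→Q, 10→R, 02→S, 20→U, 11→V, 12→W, 21→X, 22→Y), halving the
stream to `⌊ñ_tar/2⌋` symbols (an odd trailing digit rides in the archive
header). Both payloads then go through a parameter-free general-purpose
backend — bz2 (BWT-family, default) or zlib — into a self-describing
`.grass` archive ([docs/FORMAT.md](docs/FORMAT.md)) that also stores the
symbol ranking and a CRC-32 of the original input. Decompression applies
the exact inverses in reverse order and verifies the checksum.

## Worked example

A 58-residue soft-masked record (`tests/fixtures/example1.fa`):

```
>chr
ATTGCATGTcgatggATGGggaAAA
ATCGataggatAGATTTTTAAAACC
CNNNNYYY
```

`grass stages example1.fa` prints each intermediate:

```
records:      1 (fasta)
n_seq/n_spl:  58/3 (n_tar 55)
frequencies:  {'A': 18, 'C': 6, 'G': 13, 'T': 14, 'N': 4}
ranking:      least=N 2nd=C 3rd=G hfs=A 2nd_hfs=T
core:         ATTGCATGTCGATGGATGGGGAAAAATCGATAGGATAGATTTTTAAAACCCNNNN
rule1:        ATTZTZAATZTTZAZTATZTZTATZTZTZTZTAAAAATZAZTATAZTZTATAZTATTTTT
digits:       011212001211202101212101212121210000012021010212101021011111
pairs:        QWWPWVUXQXXQXXXXPPQUXQSWRRXQVVPPUUUYYYY
trailing:     None
```

Reading the output: the three lowercase runs were recorded as
(9, 6), (4, 3), (7, 7), the three Y characters as (55, 24), (1, 24),
(1, 24), the layout as 25×2, 8×1, and the block length as 58 = 55 + 3.
N, C and G are the three rarest symbols here, so rule 1 expands the
55-character core to 2·(4+6+13)+32 = 78 characters, and pairing halves
the 78-digit stream to 39 pair symbols with no trailing digit (78 is
even).
`grass verify example1.fa` exits 0, confirming the byte-exact round trip
(a 66-byte toy file is of course *smaller* than its archive; headers
dominate at this scale).

On a realistic synthetic corpus (three multi-FASTA files of four 20–40 kb
records each, soft-masked, sparse ambiguity codes):

```
$ grass bench corpus --baseline gzip
file                                     orig         comp       CR      sec
sample1.fa                             122197        35956     3.40     0.05
sample2.fa                             125115        36775     3.40     0.05
sample3.fa                             121124        35485     3.41     0.05
WACR: 3.40
CRIP vs gzip: 15.68%
```

CR is original/compressed size per file, WACR the corpus-weighted ratio
(total original / total compressed), and CRIP the percentage improvement
of one WACR over a baseline's.

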