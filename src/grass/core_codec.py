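"""Phase 2: frequency-driven grammar reduction of the core stream.

The core stream is text over five symbols (A, C, G, T, N — with U standing
in the T slot for RNA). The encoder:

1. tallies the five symbol frequencies;
2. ranks the symbols — three least frequent, plus the highest-frequency
   symbol (HFS) and the second HFS;
3. applies grammar rule 1: the least-frequent symbol becomes ``ZZ``, the
   second-least becomes ``Z`` + HFS, the third-least becomes ``Z`` +
   second HFS, shrinking the working alphabet to {HFS, second HFS, Z};
4. substitutes digits: HFS -> '0', second HFS -> '1', 'Z' -> '2';
5. applies grammar rule 2: adjacent digit pairs map to one of nine
   symbols, halving the stream (an odd trailing digit is kept aside).

With ``l <= s_l <= t_l`` the three smallest counts and ``o_l`` the sum of
the two largest, rule 1 expands the stream from ``n_tar = l+s_l+t_l+o_l``
to ``2*(l+s_l+t_l) + o_l`` characters; pairing then halves it. Every stage
has an exact inverse, applied in reverse order on decode.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, NamedTuple

from .errors import CorruptStreamError, InternalContractError

__all__ = [
    "CORE_SYMBOLS",
    "FLAG",
    "PAIR_TABLE",
    "PAIR_SYMBOLS",
    "FrequencyTable",
    "SymbolRanking",
    "count_frequencies",
    "rank_symbols",
    "rule1_mapping",
    "apply_rule1",
    "invert_rule1",
    "apply_substitution",
    "invert_substitution",
    "pair_encode",
    "pair_decode",
    "expanded_length",
    "encode_core",
    "decode_core",
]

# Fixed symbol order used for tie-breaking; the T slot holds U for RNA.
CORE_SYMBOLS = "ACGTN"
FLAG = "Z"

# Rule-2 pair table. 'T' is skipped in the output alphabet so pair symbols
# never collide with a nucleotide letter.
PAIR_TABLE = {
    "00": "P", "01": "Q", "10": "R",
    "02": "S", "20": "U", "11": "V",
    "12": "W", "21": "X", "22": "Y",
}
PAIR_INVERSE = {v: k for k, v in PAIR_TABLE.items()}
PAIR_SYMBOLS = "".join(sorted(PAIR_TABLE.values()))


@dataclass(frozen=True)
class FrequencyTable:
    """Counts of the five core symbols over a core stream."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if set(self.counts) != set(CORE_SYMBOLS):
            raise InternalContractError(
                f"frequency table must cover exactly {CORE_SYMBOLS}"
            )

    @property
    def n_tar(self) -> int:
        return sum(self.counts.values())

    def sorted_counts(self) -> list[int]:
        """Counts in ranking order: least, 2nd-least, 3rd-least, 2nd-HFS, HFS."""
        r = rank_symbols(self)
        return [self.counts[s] for s in (r.least, r.second_least, r.third_least,
                                         r.second_hfs, r.hfs)]


class SymbolRanking(NamedTuple):
    """Permutation of the core symbols by ascending frequency."""

    least: str
    second_least: str
    third_least: str
    hfs: str
    second_hfs: str


def count_frequencies(core: str) -> FrequencyTable:
    """Tally A, C, G, T, N over the core stream (U must be mapped to T first)."""
    counts = Counter(core)
    extra = set(counts) - set(CORE_SYMBOLS)
    if extra:
        raise InternalContractError(f"core stream contains non-core symbols {extra}")
    return FrequencyTable({s: counts.get(s, 0) for s in CORE_SYMBOLS})


def rank_symbols(freq: FrequencyTable) -> SymbolRanking:
    """Rank the five symbols by ascending count.

    Ties break on the fixed order A < C < G < T < N with the later symbol
    deemed less frequent, so the ranking is deterministic; it is stored in
    the archive header and never re-derived by the decoder.
    """
    order = sorted(
        CORE_SYMBOLS,
        key=lambda s: (freq.counts[s], -CORE_SYMBOLS.index(s)),
    )
    return SymbolRanking(order[0], order[1], order[2], hfs=order[4], second_hfs=order[3])


def rule1_mapping(ranking: SymbolRanking) -> dict[str, str]:
    """Substitution table of grammar rule 1 for a ranking."""
    return {
        ranking.least: FLAG + FLAG,
        ranking.second_least: FLAG + ranking.hfs,
        ranking.third_least: FLAG + ranking.second_hfs,
    }

def apply_rule1(core: str, ranking: SymbolRanking) -> str:
    mapping = rule1_mapping(ranking)
    table = str.maketrans(mapping)
    return core.translate(table)


def invert_rule1(expanded: str, ranking: SymbolRanking) -> str:
    """Left-to-right decode of the rule-1 code (exact inverse of apply_rule1).

    Bare symbols must be HFS/second-HFS; ``Z`` always starts a two-character
    codeword.
    """
    bare = {ranking.hfs, ranking.second_hfs}
    decode = {
        FLAG: ranking.least,
        ranking.hfs: ranking.second_least,
        ranking.second_hfs: ranking.third_least,
    }
    out: list[str] = []
    i = 0
    n = len(expanded)
    while i < n:
        j = expanded.find(FLAG, i)
        if j < 0:
            j = n
        seg = expanded[i:j]
        if not set(seg) <= bare:
            raise CorruptStreamError("bare symbol outside the reduced alphabet")
        out.append(seg)
        if j >= n:
            break
        if j + 1 >= n:
            raise CorruptStreamError("dangling flag symbol at end of stream")
        nxt = expanded[j + 1]
        sym = decode.get(nxt)
        if sym is None:
            raise CorruptStreamError(f"flag followed by unexpected symbol {nxt!r}")
        out.append(sym)
        i = j + 2
    return "".join(out)


def apply_substitution(expanded: str, ranking: SymbolRanking) -> str:
    """Relabel {HFS, second HFS, Z} as digits {'0', '1', '2'}."""
    if not set(expanded) <= {ranking.hfs, ranking.second_hfs, FLAG}:
        raise InternalContractError("substitution input outside the reduced alphabet")
    table = str.maketrans({ranking.hfs: "0", ranking.second_hfs: "1", FLAG: "2"})
    return expanded.translate(table)


def invert_substitution(digits: str, ranking: SymbolRanking) -> str:
    if not set(digits) <= set("012"):
        raise CorruptStreamError("digit stream outside {0,1,2}")
    table = str.maketrans({"0": ranking.hfs, "1": ranking.second_hfs, "2": FLAG})
    return digits.translate(table)


def pair_encode(digits: str) -> tuple[str, str | None]:
    """Map non-overlapping digit pairs through the nine-symbol table.

    Returns the pair stream and the odd trailing digit (or None); the
    trailing digit travels in the archive header rather than being padded.
    """
    if not set(digits) <= set("012"):
        raise InternalContractError("pair encoder input outside {0,1,2}")
    even = len(digits) & ~1
    trailing = digits[even] if len(digits) > even else None
    pairs = "".join(PAIR_TABLE[digits[i : i + 2]] for i in range(0, even, 2))
    return pairs, trailing


def pair_decode(pairs: str, trailing: str | None = None) -> str:
    """Exact inverse of :func:`pair_encode`."""
    try:
        digits = "".join(PAIR_INVERSE[p] for p in pairs)
    except KeyError as exc:
        raise CorruptStreamError(f"unknown pair symbol {exc.args[0]!r}") from None
    if trailing is not None:
        if trailing not in "012":
            raise CorruptStreamError(f"invalid trailing digit {trailing!r}")
        digits += trailing
    return digits


def expanded_length(freq: FrequencyTable) -> int:
    """Stream length after rule 1: 2*(l + s_l + t_l) + o_l."""
    l, s_l, t_l, snd_hfs, hfs = freq.sorted_counts()
    return 2 * (l + s_l + t_l) + (snd_hfs + hfs)


def encode_core(core: str) -> tuple[str, str | None, SymbolRanking]:
    """Run the full Phase-2 forward stack on a core stream.

    Returns (pair stream, trailing digit, ranking). The ranking must be
    stored alongside the payload for decoding.
    """
    freq = count_frequencies(core)
    ranking = rank_symbols(freq)
    expanded = apply_rule1(core, ranking)
    digits = apply_substitution(expanded, ranking)
    pairs, trailing = pair_encode(digits)
    return pairs, trailing, ranking


def decode_core(pairs: str, trailing: str | None, ranking: SymbolRanking) -> str:
    """Exact inverse of :func:`encode_core` given the stored ranking."""
    digits = pair_decode(pairs, trailing)
    expanded = invert_substitution(digits, ranking)
    return invert_rule1(expanded, ranking)
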