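"""Deterministic synthetic sequence files and the worked-example fixtures.

The generator emits well-formed raw/FASTA/multi-FASTA nucleotide text with
controllable structure — base composition, N and IUPAC-ambiguity rates,
lowercase (soft-masked) runs, wrap width, DNA/RNA alphabet — standing in
for real archive corpora in round-trip and benchmark tests. Randomness
comes from :class:`random.Random` (Mersenne Twister), fully determined by
the seed, so the same parameters always produce the same bytes on every
platform.

:func:`worked_example_fixtures` returns two small hand-checked fixtures used as
oracles throughout the test suite: a 58-residue soft-masked FASTA record
with known extraction products, and a frequency table with the printed
stage outputs of the grammar codec.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Any

from .core_codec import FrequencyTable, SymbolRanking
from .errors import ParameterError

__all__ = [
    "GeneratorParams",
    "generate_input",
    "worked_example_fixtures",
    "EXAMPLE1_FASTA",
    "EXAMPLE2_SEQUENCE",
]

# Ambiguity letters outside the 5-symbol core alphabet.
IUPAC_SPECIALS = "RYSWKMBDHV"


@dataclass
class GeneratorParams:
    """Knobs of the synthetic-sequence generator.

    Defaults emulate a small soft-masked GenBank-style FASTA download:
    a handful of kilobase-scale records wrapped at 60 columns, roughly
    uniform base composition, ~1% N, sparse ambiguity codes and occasional
    soft-masked (lowercase) regions averaging 20 bp.
    """

    record_count: int = 3
    length_range: tuple[int, int] = (500, 2000)
    base_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_rate: float = 0.01
    special_rate: float = 0.002
    special_alphabet: str = IUPAC_SPECIALS
    lowercase_rate: float = 0.005
    lowercase_mean_length: float = 20.0
    wrap: int | None = 60
    format: str = "fasta"  # "raw" | "fasta" | "multifasta"
    rna: bool = False
    seed: int = 0

    def validate(self) -> None:
        for rate in (self.n_rate, self.special_rate, self.lowercase_rate):
            if not 0.0 <= rate <= 1.0:
                raise ParameterError(f"rate {rate} outside [0, 1]")
        if self.record_count < 1:
            raise ParameterError("record_count must be >= 1")
        if self.length_range[0] < 1 or self.length_range[0] > self.length_range[1]:
            raise ParameterError(f"invalid length range {self.length_range}")
        if self.format not in ("raw", "fasta", "multifasta"):
            raise ParameterError(f"unknown format {self.format!r}")
        if self.format == "raw" and self.record_count != 1:
            raise ParameterError("raw format holds exactly one record")
        if self.format == "multifasta" and self.record_count < 2:
            raise ParameterError("multifasta needs at least two records")
        if self.wrap is not None and self.wrap < 1:
            raise ParameterError("wrap width must be positive")
        if any(w < 0 for w in self.base_weights) or sum(self.base_weights) <= 0:
            raise ParameterError("base weights must be non-negative, not all zero")


def _record_residues(params: GeneratorParams, rng: random.Random) -> str:
    length = rng.randint(*params.length_range)
    bases = "ACGU" if params.rna else "ACGT"
    chars = []
    for _ in range(length):
        u = rng.random()
        if u < params.special_rate and params.special_alphabet:
            chars.append(rng.choice(params.special_alphabet))
        elif u < params.special_rate + params.n_rate:
            chars.append("N")
        else:
            chars.append(rng.choices(bases, weights=params.base_weights)[0])
    # overlay lowercase runs with geometric lengths (mean lowercase_mean_length)
    if params.lowercase_rate > 0:
        p_stop = 1.0 / max(params.lowercase_mean_length, 1.0)
        i = 0
        while i < length:
            if rng.random() < params.lowercase_rate:
                run = 1
                while rng.random() > p_stop:
                    run += 1
                for j in range(i, min(i + run, length)):
                    chars[j] = chars[j].lower()
                i += run
            else:
                i += 1
    return "".join(chars)


def generate_input(params: GeneratorParams) -> bytes:
    """Generate one synthetic input file; same params (incl. seed) => same bytes."""
    params.validate()
    rng = random.Random(params.seed)
    lines: list[str] = []
    for r in range(params.record_count):
        residues = _record_residues(params, rng)
        if params.format != "raw":
            lines.append(f">synthetic_{r} len={len(residues)}")
        width = params.wrap or len(residues)
        for i in range(0, len(residues), width):
            lines.append(residues[i : i + width])
    return ("\n".join(lines) + "\n").encode("ascii")


# ---------------------------------------------------------------------------
# Worked-example fixtures
# ---------------------------------------------------------------------------

_EXAMPLE1_RESIDUES = (
    "ATTGCATGTcgatggATGGggaAAAATCGataggatAGATTTTTAAAACCCNNNNYYY"
)
# The original record is laid out wrapped at width 25 (lines 25, 25, 8),
# which is what the recorded line-length run of 25 reflects.
EXAMPLE1_FASTA = (
    ">chr\n"
    + "\n".join(_EXAMPLE1_RESIDUES[i : i + 25] for i in range(0, 58, 25))
    + "\n"
).encode("ascii")

EXAMPLE2_SEQUENCE = (
    "ATTGCATGTCGATGGATGGGGAAAAATCGATAGGATAGATTTTTAAAACCCNNNN"
)


@dataclass
class Fixture:
    name: str
    data: dict[str, Any] = field(default_factory=dict)


def worked_example_fixtures() -> dict[str, Fixture]:
    """Hand-checked fixtures with their expected intermediate products.

    ``example1`` — a soft-masked FASTA record (">chr", 58 residues wrapped
    at 25) with the expected Phase-1 products: delta-coded lowercase runs,
    delta-coded specials, line-length RLE, block length and the 55-character
    core stream.

    ``example2`` — a five-symbol frequency table with the expected ranking
    and the known stage-output prefixes of the grammar codec (rule 1,
    digit substitution, pair stream), plus the rule-1 expansion numbers.
    """
    example1 = Fixture(
        "example1",
        {
            "file": EXAMPLE1_FASTA,
            "identifier": ">chr",
            "residues": _EXAMPLE1_RESIDUES,
            "case_runs": [(9, 6), (4, 3), (7, 7)],
            "specials": [(55, 24), (1, 24), (1, 24)],
            "line_rle": [(25, 2), (8, 1)],
            "block_length": 58,
            "core": EXAMPLE2_SEQUENCE,
            "n_seq": 58,
            "n_spl": 3,
        },
    )
    freq = FrequencyTable({"A": 50, "C": 14, "G": 10, "T": 80, "N": 4})
    example2 = Fixture(
        "example2",
        {
            "frequencies": freq,
            "ranking": SymbolRanking(
                least="N", second_least="G", third_least="C",
                hfs="T", second_hfs="A",
            ),
            "sequence": EXAMPLE2_SEQUENCE,
            "rule1_prefix": "ATTZTZAATZTT",
            "digit_prefix": "1002021102",
            "pair_prefix": "RSSVS",
            "n_tar": 158,
            "expanded_total": 186,
            "added_characters": 28,
        },
    )
    return {"example1": example1, "example2": example2}
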