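"""Grammar-stage transforms: frequency, ranking, rules 1-2, substitution."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from grass import core_codec as cc
from grass.errors import CorruptStreamError, InternalContractError


def ranking_of(counts: dict[str, int]) -> cc.SymbolRanking:
    return cc.rank_symbols(cc.FrequencyTable(counts))


class TestCountFrequencies:
    def test_example_core_tally(self, example1):
        freq = cc.count_frequencies(example1["core"])
        assert freq.counts == {"A": 18, "C": 6, "G": 13, "T": 14, "N": 4}
        assert freq.n_tar == 55

    @pytest.mark.parametrize(
        "core,expected",
        [
            ("", {"A": 0, "C": 0, "G": 0, "T": 0, "N": 0}),
            ("AAAA", {"A": 4, "C": 0, "G": 0, "T": 0, "N": 0}),
        ],
    )
    def test_degenerate(self, core, expected):
        assert cc.count_frequencies(core).counts == expected

    def test_out_of_alphabet_rejected(self):
        with pytest.raises(InternalContractError):
            cc.count_frequencies("ACGU")


class TestRankSymbols:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            (
                {"A": 50, "C": 14, "G": 10, "T": 80, "N": 4},
                ("N", "G", "C", "T", "A"),
            ),
            (
                {"A": 1, "C": 1, "G": 1, "T": 1, "N": 1},
                ("N", "T", "G", "A", "C"),
            ),
            (
                {"A": 10, "C": 10, "G": 0, "T": 0, "N": 0},
                ("N", "T", "G", "A", "C"),
            ),
        ],
    )
    def test_ranking_with_tie_rule(self, counts, expected):
        r = ranking_of(counts)
        assert (r.least, r.second_least, r.third_least, r.hfs, r.second_hfs) == expected

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.integers(0, 1000), min_size=5, max_size=5))
    def test_ranking_is_a_sorted_permutation(self, values):
        counts = dict(zip("ACGTN", values))
        r = ranking_of(counts)
        assert sorted(r) == sorted("ACGTN")
        assert counts[r.least] <= counts[r.second_least] <= counts[r.third_least]
        assert counts[r.third_least] <= counts[r.second_hfs] <= counts[r.hfs]


class TestRule1:
    def test_printed_stage_output(self, example2):
        r = example2["ranking"]
        assert cc.apply_rule1("ATTGCATGT", r).startswith(example2["rule1_prefix"])
        assert cc.apply_rule1("NNNN", r) == "ZZZZZZZZ"
        assert cc.apply_rule1("", r) == ""

    def test_inverse_of_printed_output(self, example2):
        r = example2["ranking"]
        assert cc.invert_rule1("ATTZTZAATZTT", r) == "ATTGCATGT"
        assert cc.invert_rule1("ZZ", r) == r.least

    def test_z_count_invariant(self, example2):
        r = example2["ranking"]
        core = example2["sequence"]
        freq = cc.count_frequencies(core)
        expanded = cc.apply_rule1(core, r)
        l = freq.counts[r.least]
        s = freq.counts[r.second_least]
        t = freq.counts[r.third_least]
        assert expanded.count("Z") == 2 * l + s + t
        assert len(expanded) == 2 * (l + s + t) + (
            freq.counts[r.hfs] + freq.counts[r.second_hfs]
        )

    @pytest.mark.parametrize("bad", ["Z", "TZ", "ZG", "ZC", "AZN"])
    def test_corrupt_expansion_rejected(self, example2, bad):
        with pytest.raises(CorruptStreamError):
            cc.invert_rule1(bad, example2["ranking"])


class TestSubstitution:
    def test_printed_stage_output(self, example2):
        r = example2["ranking"]
        assert cc.apply_substitution("ATTZTZAATZ", r) == "1002021102"
        assert cc.apply_substitution("", r) == ""
        assert cc.apply_substitution("ZZZZ", r) == "2222"

    def test_inverse(self, example2):
        r = example2["ranking"]
        assert cc.invert_substitution("1002021102", r) == "ATTZTZAATZ"


class TestPairCoding:
    def test_printed_stage_output(self):
        pairs, trailing = cc.pair_encode("1002021102")
        assert pairs == "RSSVS" and trailing is None

    def test_odd_length_keeps_trailing_digit(self):
        assert cc.pair_encode("0") == ("", "0")
        assert cc.pair_decode("", "0") == "0"

    def test_table_skips_t(self):
        assert "T" not in cc.PAIR_SYMBOLS
        assert cc.PAIR_SYMBOLS == "PQRSUVWXY"

    def test_unknown_symbol_rejected(self):
        with pytest.raises(CorruptStreamError):
            cc.pair_decode("PTQ")

    @settings(max_examples=300, deadline=None)
    @given(st.text(alphabet="012", max_size=100))
    def test_roundtrip_property(self, digits):
        pairs, trailing = cc.pair_encode(digits)
        assert len(pairs) == len(digits) // 2
        assert (trailing is not None) == (len(digits) % 2 == 1)
        assert cc.pair_decode(pairs, trailing) == digits


class TestExpandedLength:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"A": 50, "C": 14, "G": 10, "T": 80, "N": 4}, 186),
            ({"A": 0, "C": 0, "G": 0, "T": 0, "N": 0}, 0),
            ({"A": 1, "C": 1, "G": 1, "T": 1, "N": 1}, 8),
        ],
    )
    def test_formula(self, counts, expected):
        assert cc.expanded_length(cc.FrequencyTable(counts)) == expected

    @settings(max_examples=200, deadline=None)
    @given(st.text(alphabet="ACGTN", max_size=200))
    def test_matches_actual_expansion(self, core):
        freq = cc.count_frequencies(core)
        ranking = cc.rank_symbols(freq)
        assert len(cc.apply_rule1(core, ranking)) == cc.expanded_length(freq)


class TestFullStack:
    @settings(max_examples=300, deadline=None)
    @given(st.text(alphabet="ACGTN", max_size=150))
    def test_encode_decode_identity(self, core):
        pairs, trailing, ranking = cc.encode_core(core)
        assert set(pairs) <= set(cc.PAIR_SYMBOLS)
        assert cc.decode_core(pairs, trailing, ranking) == core

    def test_many_random_cores(self):
        """Per-stage inverse identity over ten thousand random streams."""
        rng = random.Random(20240917)
        from conftest import random_core

        for _ in range(10_000):
            core = random_core(rng, max_len=40)
            freq = cc.count_frequencies(core)
            ranking = cc.rank_symbols(freq)
            expanded = cc.apply_rule1(core, ranking)
            assert cc.invert_rule1(expanded, ranking) == core
            digits = cc.apply_substitution(expanded, ranking)
            assert cc.invert_substitution(digits, ranking) == expanded
            pairs, trailing = cc.pair_encode(digits)
            assert len(pairs) == len(digits) // 2
            assert cc.pair_decode(pairs, trailing) == digits


def count_rule1_parses_exhaustively(ranking, max_len: int):
    """DFS over every string on the reduced 3-symbol alphabet up to max_len.

    Carries the parse-count recurrence f[k] = [bare] f[k-1] + [pair] f[k-2]
    (codewords: bare HFS/second-HFS, or 'Z' followed by any of the three).
    Returns the maximum parse count seen over all strings, checking every
    prefix; subtrees where no parse can ever complete are pruned.
    """
    alphabet = (ranking.hfs, ranking.second_hfs, "Z")
    bare = {ranking.hfs, ranking.second_hfs}
    max_count = 0

    # stack entries: (depth, prev_char, f_km1, f_km2)
    stack = [(0, "", 1, 0)]
    while stack:
        depth, prev, f1, f2 = stack.pop()
        max_count = max(max_count, f1)
        assert f1 <= 1, "a string admits two rule-1 decodings"
        if depth == max_len or (f1 == 0 and f2 == 0):
            continue
        for ch in alphabet:
            f = (f1 if ch in bare else 0) + (f2 if prev == "Z" else 0)
            stack.append((depth + 1, ch, f, f1))
    return max_count


def test_rule1_code_uniquely_decodable(example2):
    """No 3-symbol string of length <= 12 decodes two ways under rule 1."""
    assert count_rule1_parses_exhaustively(example2["ranking"], 12) == 1


def test_rule1_brute_force_agrees_with_decoder(example2):
    """invert_rule1 returns the unique parse exactly when one exists."""
    import itertools

    r = example2["ranking"]
    mapping = {v: k for k, v in cc.rule1_mapping(r).items()}
    alphabet = (r.hfs, r.second_hfs, "Z")

    def brute_parses(s):
        if s == "":
            return [""]
        out = []
        if s[0] in (r.hfs, r.second_hfs):
            out.extend(s[0] + rest for rest in brute_parses(s[1:]))
        if s[:2] in mapping:
            out.extend(mapping[s[:2]] + rest for rest in brute_parses(s[2:]))
        return out

    for n in range(0, 9):
        for tup in itertools.product(alphabet, repeat=n):
            s = "".join(tup)
            parses = brute_parses(s)
            assert len(parses) <= 1
            if parses:
                assert cc.invert_rule1(s, r) == parses[0]
            else:
                with pytest.raises(CorruptStreamError):
                    cc.invert_rule1(s, r)
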