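"""Similarity measures against independent brute-force oracles and the
symmetry / self-similarity / range axioms."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest

from kinleak import chemsim
from kinleak.chemsim import (RDKitBackend, StructureBackend, all_similarities,
                             fit_idf, get_similarity, sim_clcs, sim_edit,
                             sim_lingo, sim_maccs_dice, sim_mcs, sim_substring,
                             sim_tf, sim_tfidf, similarity_matrix)
from kinleak.synthetic import GeneratorConfig, generate_inhibitors


# ---------------------------------------------------------------------------
# brute-force oracles (enumeration, independent of the DP implementations)
# ---------------------------------------------------------------------------

def edit_distance_recursive(a, b):
    """The recursive definition of Levenshtein distance."""
    import functools

    @functools.lru_cache(maxsize=None)
    def d(i, j):
        if i == 0:
            return j
        if j == 0:
            return i
        return min(d(i - 1, j) + 1, d(i, j - 1) + 1,
                   d(i - 1, j - 1) + (a[i - 1] != b[j - 1]))

    return d(len(a), len(b))


def lcs_bruteforce(a, b):
    """Longest common subsequence by enumerating all subsequences of a."""
    best = 0
    for r in range(len(a), 0, -1):
        for combo in itertools.combinations(a, r):
            sub = "".join(combo)
            it = iter(b)
            if all(ch in it for ch in sub):
                return r
    return best


def longest_common_substring_bruteforce(a, b):
    return max((j - i for i in range(len(a)) for j in range(i, len(a) + 1)
                if a[i:j] in b), default=0)


def common_prefix_bruteforce(a, b):
    n = 0
    while n < min(len(a), len(b)) and a[n] == b[n]:
        n += 1
    return n


def clcs_oracle(a, b):
    norm = len(a) * len(b)
    return (lcs_bruteforce(a, b) ** 2 / norm
            + common_prefix_bruteforce(a, b) ** 2 / norm
            + longest_common_substring_bruteforce(a, b) ** 2 / norm) / 3


def substring_cosine_oracle(a, b):
    def all_substrings(s):
        return Counter(s[i:j] for i in range(len(s))
                       for j in range(i + 2, len(s) + 1))
    ca, cb = all_substrings(a), all_substrings(b)
    dot = sum(v * cb[k] for k, v in ca.items())
    na = math.sqrt(sum(v * v for v in ca.values()))
    nb = math.sqrt(sum(v * v for v in cb.values()))
    return dot / (na * nb) if na and nb else 0.0


def _string_pairs():
    """Exhaustive pairs up to length 4 over a 3-letter alphabet, plus a seeded
    sample of longer pairs (up to length 8)."""
    alphabet = "ABC"
    short = []
    for L in range(1, 5):
        short.extend("".join(p) for p in itertools.product(alphabet, repeat=L))
    pairs = list(itertools.combinations_with_replacement(short, 2))
    rng = np.random.default_rng(99)
    for _ in range(300):
        la, lb = rng.integers(5, 9, size=2)
        a = "".join(rng.choice(list(alphabet), size=la))
        b = "".join(rng.choice(list(alphabet), size=lb))
        pairs.append((a, b))
    return pairs


class TestStringOraclesExhaustive:
    @pytest.fixture(scope="class")
    def pairs(self):
        return _string_pairs()

    def test_edit_matches_recursive_definition(self, pairs):
        for a, b in pairs:
            expected = 1 - edit_distance_recursive(a, b) / max(len(a), len(b))
            assert sim_edit(a, b) == pytest.approx(expected, abs=1e-12)

    def test_edit_agrees_with_edlib(self, pairs):
        edlib = pytest.importorskip("edlib")
        for a, b in pairs[:500]:
            d = edlib.align(a, b, task="distance")["editDistance"]
            assert sim_edit(a, b) == pytest.approx(
                1 - d / max(len(a), len(b)), abs=1e-12)

    def test_clcs_matches_enumeration(self, pairs):
        for a, b in pairs:
            assert sim_clcs(a, b) == pytest.approx(clcs_oracle(a, b), abs=1e-12)

    def test_substring_matches_enumeration(self, pairs):
        for a, b in pairs:
            if len(a) < 2 or len(b) < 2:
                continue
            assert sim_substring(a, b) == pytest.approx(
                substring_cosine_oracle(a, b), abs=1e-12)


class TestHandExamples:
    def test_edit_kitten_sitting(self):
        assert sim_edit("kitten", "sitting") == pytest.approx(1 - 3 / 7, abs=1e-4)

    def test_edit_trivial(self):
        assert sim_edit("CCO", "CCO") == 1.0
        assert sim_edit("A", "B") == 0.0

    def test_clcs_abcd_acd(self):
        # LCS=3, prefix=1, substring=2 -> (9/12 + 1/12 + 4/12) / 3
        assert sim_clcs("ABCD", "ACD") == pytest.approx(0.38889, abs=1e-4)
        assert sim_clcs("AB", "CD") == 0.0

    def test_lingo_counts(self):
        assert sim_lingo("CCO", "CCN", q=3) == 0.0
        assert sim_lingo("CCCC", "CCC", q=3) == pytest.approx(2 / 3)
        assert sim_lingo("CCOCCO", "CCOCCO", q=4) == 1.0

    def test_lingo_short_string_warns_zero(self):
        with pytest.warns(UserWarning):
            assert sim_lingo("CC", "CCO", q=3) == 0.0

    def test_substring_abab_ab(self):
        assert sim_substring("ABAB", "AB") == pytest.approx(2 / math.sqrt(8),
                                                            abs=1e-6)
        assert sim_substring("AB", "CD") == 0.0

    def test_tf_4grams(self):
        # a={ABCD, BCDE}, b={ABCD, BCDX}: one shared gram -> cosine 1/2
        assert sim_tf("ABCDE", "ABCDX") == pytest.approx(0.5)
        assert sim_tf("ABCD", "WXYZ") == 0.0

    def test_idf_formula(self):
        idf = fit_idf(["AAAA", "BBBB", "CCCC"])  # N=3, each gram in 1 doc
        assert idf["AAAA"] == pytest.approx(math.log(4 / 2) + 1, abs=1e-4)

    def test_tfidf_self_and_disjoint(self):
        idf = fit_idf(["ABCDEF", "BCDEFG"])
        assert sim_tfidf("ABCDE", "ABCDE", idf) == pytest.approx(1.0)
        assert sim_tfidf("ABCD", "WXYZ", idf) == 0.0

    def test_tfidf_requires_fit(self):
        f = get_similarity("tfidf")
        with pytest.raises(RuntimeError):
            f("CCCC", "CCCC")


class MockBackend(StructureBackend):
    """Fixed key sets / sizes, for checking the formulas in isolation."""

    def __init__(self, keys, sizes, mcs):
        self._keys, self._sizes, self._mcs = keys, sizes, mcs

    def maccs_keys(self, s):
        return frozenset(self._keys[s])

    def mol_size(self, s):
        return self._sizes[s]

    def mcs_atoms_bonds(self, a, b):
        return self._mcs[frozenset((a, b))]


class TestStructuralMeasures:
    def test_dice_on_fixed_key_sets(self):
        be = MockBackend({"a": {1, 2, 3}, "b": {2, 3, 4}, "c": set()},
                         {}, {})
        assert sim_maccs_dice("a", "b", be) == pytest.approx(2 * 2 / 6)
        assert sim_maccs_dice("a", "a", be) == 1.0
        assert sim_maccs_dice("c", "c", be) == 1.0  # both empty

    def test_dice_disjoint(self):
        be = MockBackend({"a": {1}, "b": {2}}, {}, {})
        assert sim_maccs_dice("a", "b", be) == 0.0

    def test_mcs_ethane_propane(self):
        # common subgraph of the two path graphs: 2 atoms + 1 bond
        be = RDKitBackend()
        assert sim_mcs("CC", "CCC", be) == pytest.approx(3 / 5)
        assert sim_mcs("CCC", "CCC", be) == 1.0

    def test_mcs_no_common_atoms(self):
        be = MockBackend({}, {"a": (2, 1), "b": (3, 2)},
                         {frozenset(("a", "b")): (0, 0)})
        assert sim_mcs("a", "b", be) == 0.0

    def test_unparseable_smiles_raises(self):
        be = RDKitBackend()
        with pytest.raises(ValueError):
            sim_maccs_dice("not_a_smiles((", "CC", be)


class TestAxiomsOnGeneratedSmiles:
    """Symmetry, self-similarity 1 and range [0,1] for all ten measures over
    pairs of generated, chemically valid SMILES."""

    @pytest.fixture(scope="class")
    def measures(self):
        backend = RDKitBackend()
        ms = all_similarities(backend)
        cfg = GeneratorConfig(seed=11)
        smiles, _ = generate_inhibitors(cfg)
        ms["tfidf"].fit(list(smiles.values()))
        return ms, list(smiles.values())

    @pytest.mark.parametrize("name", chemsim.MEASURE_NAMES)
    def test_axioms(self, measures, name):
        ms, smiles = measures
        f = ms[name]
        rng = np.random.default_rng(hash(name) % 2**31)
        n_pairs = 60 if name == "mcs" else 120
        for _ in range(n_pairs):
            a, b = (smiles[i] for i in rng.integers(0, len(smiles), size=2))
            s_ab = f(a, b)
            assert 0.0 <= s_ab <= 1.0 + 1e-12
            assert f(b, a) == pytest.approx(s_ab, abs=1e-12)  # symmetry
        for a in smiles[:20]:
            assert f(a, a) == pytest.approx(1.0, abs=1e-12)


class TestSimilarityMatrix:
    def test_symmetric_unit_diagonal(self):
        ids, mat = similarity_matrix({"a": "CCO", "b": "CCN", "c": "CCCC"},
                                     get_similarity("edit"))
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 1.0)
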