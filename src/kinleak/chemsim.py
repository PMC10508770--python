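"""Ten inhibitor-similarity measures, each symmetric and valued in [0, 1].

Two are structure-based (MACCS-key Dice, maximum-common-substructure
Tanimoto) and go through a pluggable :class:`StructureBackend`, so the string
kernels carry no chemistry dependency and the structural ones can be mocked.
The other eight operate directly on the SMILES text:

========== =================================================================
edit        1 - Levenshtein distance / max length
clcs        mean of three squared-normalized longest-common-subsequence
            components (subsequence, common prefix, common substring)
lingo3/4/5  q-gram count agreement, averaged over the union of q-grams
substring   cosine over counts of all substrings of length >= 2
tf          cosine over 4-gram counts
tfidf       cosine over 4-gram tf-idf vectors, idf fitted on training SMILES
========== =================================================================

The normalizations (cosine for the frequency kernels, Tanimoto over
atoms+bonds for MCS, the equal-weight three-component CLCS) follow the common
choices of the SMILES string-kernel literature; each sits behind its own
function so alternatives are a local change.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

MEASURE_NAMES = ("maccs_dice", "mcs", "edit", "clcs", "lingo3", "lingo4",
                 "lingo5", "substring", "tf", "tfidf")

__all__ = ["MEASURE_NAMES", "StructureBackend", "RDKitBackend",
           "SimilarityFunction", "get_similarity", "all_similarities",
           "sim_maccs_dice", "sim_mcs", "sim_edit", "sim_clcs", "sim_lingo",
           "sim_substring", "sim_tf", "fit_idf", "sim_tfidf",
           "similarity_matrix"]


# ---------------------------------------------------------------------------
# structure backend
# ---------------------------------------------------------------------------

class StructureBackend:
    """Contract for the chemistry the two structural measures need.

    ``maccs_keys(smiles)`` returns the set of on-bit indices of the 166-key
    MACCS substructure fingerprint; ``mol_size(smiles)`` the (heavy-atom,
    bond) counts; ``mcs_atoms_bonds(a, b)`` the atom and bond counts of the
    maximum common substructure.
    """

    def maccs_keys(self, smiles: str) -> frozenset:
        raise NotImplementedError

    def mol_size(self, smiles: str) -> tuple[int, int]:
        raise NotImplementedError

    def mcs_atoms_bonds(self, a: str, b: str) -> tuple[int, int]:
        raise NotImplementedError


class RDKitBackend(StructureBackend):
    """RDKit-based backend (MACCS keys, FMCS search)."""

    def __init__(self, mcs_timeout: int = 10):
        self.mcs_timeout = mcs_timeout
        from rdkit import RDLogger
        RDLogger.DisableLog("rdApp.*")

    @staticmethod
    @lru_cache(maxsize=4096)
    def _mol(smiles: str):
        from rdkit import Chem
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smiles!r}")
        return mol

    @lru_cache(maxsize=4096)
    def maccs_keys(self, smiles: str) -> frozenset:
        from rdkit.Chem import MACCSkeys
        fp = MACCSkeys.GenMACCSKeys(self._mol(smiles))
        return frozenset(fp.GetOnBits())

    def mol_size(self, smiles: str) -> tuple[int, int]:
        mol = self._mol(smiles)
        return mol.GetNumAtoms(), mol.GetNumBonds()

    @lru_cache(maxsize=16384)
    def _mcs_cached(self, a: str, b: str) -> tuple[int, int]:
        from rdkit.Chem import rdFMCS
        res = rdFMCS.FindMCS([self._mol(a), self._mol(b)],
                             timeout=self.mcs_timeout)
        return res.numAtoms, res.numBonds

    def mcs_atoms_bonds(self, a: str, b: str) -> tuple[int, int]:
        if b < a:  # canonical order so the cache is symmetric
            a, b = b, a
        return self._mcs_cached(a, b)


# ---------------------------------------------------------------------------
# structural measures
# ---------------------------------------------------------------------------

def sim_maccs_dice(a: str, b: str, backend: StructureBackend) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|) over MACCS key sets; 1 when both
    molecules set no keys at all."""
    ka, kb = backend.maccs_keys(a), backend.maccs_keys(b)
    denom = len(ka) + len(kb)
    if denom == 0:
        return 1.0
    return 2.0 * len(ka & kb) / denom


def sim_mcs(a: str, b: str, backend: StructureBackend) -> float:
    """Tanimoto over atoms+bonds of the maximum common substructure:
    m / (s_a + s_b - m) with s = atoms + bonds."""
    na, nb_ = backend.mcs_atoms_bonds(a, b)
    m = na + nb_
    sa = sum(backend.mol_size(a))
    sb = sum(backend.mol_size(b))
    if m == 0:
        return 0.0
    return m / (sa + sb - m)


# ---------------------------------------------------------------------------
# string primitives
# ---------------------------------------------------------------------------

def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insert / delete / substitute)."""
    if len(a) < len(b):
        a, b = b, a
    prev = np.arange(len(b) + 1)
    for i, ca in enumerate(a, start=1):
        cur = np.empty(len(b) + 1, dtype=np.int64)
        cur[0] = i
        for j, cb in enumerate(b, start=1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1,
                         prev[j - 1] + (ca != cb))
        prev = cur
    return int(prev[-1])


def lcs_length(a: str, b: str) -> int:
    """Length of the longest common subsequence."""
    prev = np.zeros(len(b) + 1, dtype=np.int64)
    for ca in a:
        cur = np.zeros(len(b) + 1, dtype=np.int64)
        for j, cb in enumerate(b, start=1):
            cur[j] = prev[j - 1] + 1 if ca == cb else max(prev[j], cur[j - 1])
        prev = cur
    return int(prev[-1])


def common_prefix_length(a: str, b: str) -> int:
    n = 0
    for ca, cb in zip(a, b):
        if ca != cb:
            break
        n += 1
    return n


def longest_common_substring(a: str, b: str) -> int:
    """Length of the longest contiguous common substring."""
    best = 0
    prev = np.zeros(len(b) + 1, dtype=np.int64)
    for ca in a:
        cur = np.zeros(len(b) + 1, dtype=np.int64)
        for j, cb in enumerate(b, start=1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = int(cur[j])
        prev = cur
    return best


def _qgrams(s: str, q: int) -> Counter:
    return Counter(s[i:i + q] for i in range(len(s) - q + 1))


def _cosine(ca: Counter, cb: Counter) -> float:
    if not ca or not cb:
        return 0.0
    dot = sum(v * cb[k] for k, v in ca.items() if k in cb)
    na = math.sqrt(sum(v * v for v in ca.values()))
    nb = math.sqrt(sum(v * v for v in cb.values()))
    return dot / (na * nb)


# ---------------------------------------------------------------------------
# string measures
# ---------------------------------------------------------------------------

def sim_edit(a: str, b: str) -> float:
    """1 - levenshtein(a, b) / max(len(a), len(b))."""
    if not a or not b:
        raise ValueError("edit similarity needs non-empty strings")
    return 1.0 - levenshtein(a, b) / max(len(a), len(b))


def sim_clcs(a: str, b: str) -> float:
    """Combination-of-LCS similarity: mean of three squared-normalized
    components — full LCS, longest common prefix, longest common substring."""
    if not a or not b:
        raise ValueError("clcs needs non-empty strings")
    norm = len(a) * len(b)
    v1 = lcs_length(a, b) ** 2 / norm
    v2 = common_prefix_length(a, b) ** 2 / norm
    v3 = longest_common_substring(a, b) ** 2 / norm
    return (v1 + v2 + v3) / 3.0


def sim_lingo(a: str, b: str, q: int = 4) -> float:
    """LINGO similarity over q-character substrings: the mean, over the
    distinct q-grams of either string, of 1 - |N_a - N_b| / (N_a + N_b)."""
    if len(a) < q or len(b) < q:
        warnings.warn(f"lingo{q}: string shorter than q, similarity defined as 0")
        return 0.0
    ca, cb = _qgrams(a, q), _qgrams(b, q)
    grams = set(ca) | set(cb)
    total = sum(1.0 - abs(ca[g] - cb[g]) / (ca[g] + cb[g]) for g in grams)
    return total / len(grams)


def sim_substring(a: str, b: str, max_len: int | None = None) -> float:
    """Cosine similarity of count vectors over all substrings of length >= 2
    (optionally capped at ``max_len``)."""
    if len(a) < 2 or len(b) < 2:
        warnings.warn("substring similarity: string shorter than 2, defined as 0")
        return 0.0

    def counts(s: str) -> Counter:
        top = len(s) if max_len is None else min(max_len, len(s))
        c: Counter = Counter()
        for q in range(2, top + 1):
            c.update(_qgrams(s, q))
        return c

    return _cosine(counts(a), counts(b))


def sim_tf(a: str, b: str) -> float:
    """Cosine similarity of 4-gram count (term-frequency) vectors."""
    if len(a) < 4 or len(b) < 4:
        warnings.warn("tf similarity: string shorter than 4, defined as 0")
        return 0.0
    return _cosine(_qgrams(a, 4), _qgrams(b, 4))


def fit_idf(training_smiles) -> dict:
    """Smoothed inverse document frequency over 4-grams of the training
    corpus: idf(g) = ln((1+N)/(1+df(g))) + 1.  Fit on training-fold SMILES
    only — fitting on the full dataset would itself leak test information."""
    docs = list(training_smiles)
    if not docs:
        raise ValueError("cannot fit idf on an empty corpus")
    n = len(docs)
    df: Counter = Counter()
    for s in docs:
        df.update(set(_qgrams(s, 4)))
    idf = {g: math.log((1 + n) / (1 + d)) + 1.0 for g, d in df.items()}
    idf["__N__"] = n  # kept so unseen grams get the df=0 weight
    return idf


def sim_tfidf(a: str, b: str, idf: dict) -> float:
    """Cosine similarity of 4-gram tf-idf vectors under a fitted idf table."""
    if len(a) < 4 or len(b) < 4:
        warnings.warn("tfidf similarity: string shorter than 4, defined as 0")
        return 0.0
    n = idf.get("__N__", 0)
    default = math.log(1 + n) + 1.0  # df = 0
    wa = Counter({g: c * idf.get(g, default) for g, c in _qgrams(a, 4).items()})
    wb = Counter({g: c * idf.get(g, default) for g, c in _qgrams(b, 4).items()})
    return _cosine(wa, wb)


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

@dataclass
class SimilarityFunction:
    """A named, symmetric, [0,1]-valued similarity over SMILES strings."""

    name: str
    _func: object = field(repr=False)
    requires_fit: bool = False
    _fitted: bool = False

    def fit(self, training_smiles) -> "SimilarityFunction":
        if self.requires_fit:
            idf = fit_idf(training_smiles)
            self._func = lambda a, b: sim_tfidf(a, b, idf)
            self._fitted = True
        return self

    def __call__(self, a: str, b: str) -> float:
        if self.requires_fit and not self._fitted:
            raise RuntimeError(f"{self.name} must be fitted on training SMILES first")
        return float(self._func(a, b))


def get_similarity(name: str, backend: StructureBackend | None = None
                   ) -> SimilarityFunction:
    """Look up one of the ten measures by name.  Structural measures require a
    backend (``RDKitBackend()`` by default); ``tfidf`` must be ``fit()`` on
    the training SMILES before use."""
    if name in ("maccs_dice", "mcs"):
        backend = backend or RDKitBackend()
        func = {"maccs_dice": sim_maccs_dice, "mcs": sim_mcs}[name]
        return SimilarityFunction(name, lambda a, b: func(a, b, backend))
    if name == "edit":
        return SimilarityFunction(name, sim_edit)
    if name == "clcs":
        return SimilarityFunction(name, sim_clcs)
    if name in ("lingo3", "lingo4", "lingo5"):
        q = int(name[-1])
        return SimilarityFunction(name, lambda a, b: sim_lingo(a, b, q))
    if name == "substring":
        return SimilarityFunction(name, sim_substring)
    if name == "tf":
        return SimilarityFunction(name, sim_tf)
    if name == "tfidf":
        return SimilarityFunction(name, None, requires_fit=True)
    raise ValueError(f"unknown similarity measure {name!r}; "
                     f"expected one of {MEASURE_NAMES}")


def all_similarities(backend: StructureBackend | None = None) -> dict:
    """name -> SimilarityFunction for all ten measures (tfidf unfitted)."""
    backend = backend or RDKitBackend()
    return {name: get_similarity(name, backend) for name in MEASURE_NAMES}


def similarity_matrix(smiles_by_id: dict, measure: SimilarityFunction):
    """Dense symmetric similarity matrix over an inhibitor library.

    Returns (ids, matrix) with matrix[i, j] = measure(smiles_i, smiles_j);
    only the upper triangle is computed.
    """
    ids = list(smiles_by_id)
    n = len(ids)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = measure(smiles_by_id[ids[i]],
                                            smiles_by_id[ids[j]])
    return ids, mat
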