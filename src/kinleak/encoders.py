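"""Integer encoding of SMILES and KLIFS strings, and the junk-token control.

Both model inputs are fixed-length integer vectors: 90 positions for SMILES,
85 for the KLIFS pocket sequence.  Index 0 is reserved for padding; the KLIFS
vocabulary carries a dedicated gap symbol for missing pocket residues.

The junk-SMILES control replaces every inhibitor's SMILES with a random string
of the same length drawn from the SMILES character set.  Each inhibitor keeps
one constant, unique junk string, so the string carries inhibitor *identity*
but no chemical content — the control that separates token memorization from
actual structure reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import KLIFS_GAP

SMILES_LENGTH = 90
KLIFS_LENGTH = 85

#: canonical SMILES character set: organic-subset atoms (with the second
#: letters of Cl/Br), aromatic forms, hydrogens, ring digits, bonds, branches,
#: brackets, charges, stereo markers
CANONICAL_SMILES_CHARS = tuple(
    "BCNOPSFI" "bcnops" "lrH" "0123456789" "()[]=#-+/\\@.%"
)

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

PAD_INDEX = 0


class EncodingError(ValueError):
    pass


@dataclass
class Vocabulary:
    """Dense symbol -> index map with index 0 reserved for padding."""

    index: dict = field(default_factory=dict)
    unknown_index: int | None = None

    @classmethod
    def from_symbols(cls, symbols, add_unknown: bool = False) -> "Vocabulary":
        seen = {}
        for s in symbols:
            if s not in seen:
                seen[s] = len(seen) + 1  # 0 is padding
        vocab = cls(index=seen)
        if add_unknown:
            vocab.unknown_index = len(seen) + 1
        return vocab

    @classmethod
    def smiles_default(cls, corpus=()) -> "Vocabulary":
        """Fixed canonical SMILES alphabet, extended by any extra characters
        observed in ``corpus`` (stable indices: canonical set first)."""
        extra = sorted({ch for s in corpus for ch in s}
                       - set(CANONICAL_SMILES_CHARS))
        return cls.from_symbols(list(CANONICAL_SMILES_CHARS) + extra)

    @classmethod
    def klifs_default(cls) -> "Vocabulary":
        """20 amino-acid letters plus the gap symbol for missing residues."""
        return cls.from_symbols(list(AMINO_ACIDS) + [KLIFS_GAP])

    def __len__(self) -> int:
        return len(self.index) + 1 + (self.unknown_index is not None)

    @property
    def size(self) -> int:
        return len(self)

    def symbols(self) -> list:
        return list(self.index)

    def decode(self, vec) -> str:
        rev = {i: s for s, i in self.index.items()}
        out = []
        for i in np.asarray(vec):
            if i == PAD_INDEX:
                break
            out.append(rev[int(i)])
        return "".join(out)

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"<pad>\t{PAD_INDEX}\n")
            for s, i in sorted(self.index.items(), key=lambda kv: kv[1]):
                fh.write(f"{s}\t{i}\n")

    @classmethod
    def from_text(cls, path) -> "Vocabulary":
        index = {}
        with open(path) as fh:
            for line in fh:
                sym, i = line.rstrip("\n").split("\t")
                if sym == "<pad>":
                    continue
                index[sym] = int(i)
        return cls(index=index)


def encode_string(s: str, vocab: Vocabulary, target_len: int,
                  strict: bool = True) -> np.ndarray:
    """Map a string to a length-``target_len`` integer vector, padding with 0.

    Unknown characters raise in strict mode; in lenient mode they map to the
    vocabulary's unknown index (which must be enabled).
    """
    if len(s) > target_len:
        raise EncodingError(
            f"string of length {len(s)} exceeds target length {target_len}")
    vec = np.zeros(target_len, dtype=np.int64)
    for i, ch in enumerate(s):
        idx = vocab.index.get(ch)
        if idx is None:
            if strict or vocab.unknown_index is None:
                raise EncodingError(f"character {ch!r} not in vocabulary")
            idx = vocab.unknown_index
        vec[i] = idx
    return vec


def encode_pairs(smiles_list, klifs_list, smiles_vocab: Vocabulary,
                 klifs_vocab: Vocabulary,
                 smiles_len: int = SMILES_LENGTH,
                 klifs_len: int = KLIFS_LENGTH) -> tuple[np.ndarray, np.ndarray]:
    """Vectorize parallel lists of SMILES and KLIFS strings."""
    xs = np.stack([encode_string(s, smiles_vocab, smiles_len) for s in smiles_list])
    xk = np.stack([encode_string(k, klifs_vocab, klifs_len) for k in klifs_list])
    return xs, xk


def make_junk_smiles(smiles_by_inhibitor: dict, seed: int,
                     alphabet=CANONICAL_SMILES_CHARS,
                     max_attempts: int = 1000) -> dict:
    """Build the constant junk-token map: inhibitor_id -> random string.

    Each junk string has the same length as the inhibitor's real SMILES, with
    characters drawn independently and uniformly from the SMILES alphabet.
    Strings are pairwise distinct (collisions are redrawn), so every inhibitor
    receives a unique identity token.  Deterministic given ``seed`` and the
    (insertion-ordered) input map.
    """
    rng = np.random.default_rng(seed)
    alphabet = list(alphabet)
    out: dict = {}
    used: set = set()
    for inhib_id, smiles in smiles_by_inhibitor.items():
        if len(smiles) == 0:
            raise ValueError(f"empty SMILES for inhibitor {inhib_id!r}")
        for _ in range(max_attempts):
            junk = "".join(rng.choice(alphabet, size=len(smiles)))
            if junk not in used:
                break
        else:
            raise RuntimeError(
                f"could not draw a unique junk string for {inhib_id!r}: "
                "alphabet too small for the number of inhibitors")
        used.add(junk)
        out[inhib_id] = junk
    return out
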