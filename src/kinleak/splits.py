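"""Train/validation/test partitioning under three schemes.

``standard``      — each measurement assigned independently at random
                    (80/10/10 by default): the conventional split, and the one
                    most exposed to information leakage through shared
                    inhibitors and homologous kinases.
``by_inhibitor``  — all measurements of a compound confined to one fold, so
                    test compounds are never seen in training.
``by_group``      — the generic grouped split: supply any record -> group map
                    (kinase id, chemical scaffold, cluster id, ...) and no
                    group straddles two folds.  ``by_inhibitor`` is the special
                    case group = inhibitor.

Fold sizes use largest-remainder rounding, so the 80/10/10 statement is exact
whenever n is divisible.  All schemes draw from a dedicated random stream, so
assignments depend only on (scheme, seed, table order).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FOLDS = ("train", "validation", "test")
DEFAULT_FRACTIONS = (0.8, 0.1, 0.1)


@dataclass
class SplitAssignment:
    """Per-record fold membership plus the provenance that produced it."""

    folds: np.ndarray            # array of 'train'/'validation'/'test', one per record
    scheme: str = "standard"
    seed: int = 0
    fractions: tuple = DEFAULT_FRACTIONS
    group_of: np.ndarray | None = None

    def __post_init__(self):
        self.folds = np.asarray(self.folds, dtype=object)
        bad = set(self.folds) - set(FOLDS)
        if bad:
            raise ValueError(f"unknown fold labels: {bad}")

    def indices(self, fold: str) -> np.ndarray:
        if fold not in FOLDS:
            raise ValueError(f"unknown fold {fold!r}")
        return np.flatnonzero(self.folds == fold)

    def counts(self) -> dict:
        return {f: int((self.folds == f).sum()) for f in FOLDS}

    def __len__(self) -> int:
        return len(self.folds)

    def to_frame(self, table=None) -> pd.DataFrame:
        df = pd.DataFrame({"record_index": np.arange(len(self.folds)),
                           "fold": self.folds})
        if table is not None:
            df["kinase_id"] = table.df["kinase_id"].to_numpy()
            df["inhibitor_id"] = table.df["inhibitor_id"].to_numpy()
        return df

    def to_csv(self, path, table=None) -> None:
        self.to_frame(table).to_csv(path, index=False)


def _check_fractions(fractions) -> np.ndarray:
    fr = np.asarray(fractions, dtype=float)
    if fr.shape != (3,) or np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be three non-negative numbers summing to 1")
    return fr


def _largest_remainder(n: int, fractions: np.ndarray) -> np.ndarray:
    """Integer fold sizes summing to n, deterministic largest-remainder rule."""
    raw = fractions * n
    sizes = np.floor(raw).astype(int)
    remainder = raw - sizes
    # ties broken by fold order (train first), stable argsort on -remainder
    for i in np.argsort(-remainder, kind="stable")[: n - sizes.sum()]:
        sizes[i] += 1
    return sizes


def split_standard(table, seed: int,
                   fractions=DEFAULT_FRACTIONS) -> SplitAssignment:
    """Randomly assign individual records to folds (seeded shuffle, then
    contiguous slices sized by largest remainder)."""
    fr = _check_fractions(fractions)
    n = len(table)
    if n < 10:
        raise ValueError(f"need at least 10 records, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    sizes = _largest_remainder(n, fr)
    folds = np.empty(n, dtype=object)
    start = 0
    for fold, size in zip(FOLDS, sizes):
        folds[order[start:start + size]] = fold
        start += size
    return SplitAssignment(folds, scheme="standard", seed=seed,
                           fractions=tuple(fr))


def split_by_group(table, group_of, seed: int,
                   fractions=DEFAULT_FRACTIONS,
                   scheme_name: str = "by_group") -> SplitAssignment:
    """Grouped split: shuffle the distinct groups and fill folds by *group*
    count (largest remainder), so every group lands intact in exactly one fold.

    ``group_of`` maps each record to its group: either an array-like of
    per-record group ids, or a dict keyed by record index.
    """
    fr = _check_fractions(fractions)
    n = len(table)
    if isinstance(group_of, dict):
        groups = np.asarray([group_of[i] for i in range(n)], dtype=object)
    else:
        groups = np.asarray(group_of, dtype=object)
        if len(groups) != n:
            raise ValueError("group map must cover every record")
    uniq = pd.unique(groups)  # first-appearance order: stable w.r.t. table order
    n_nonempty = int(np.count_nonzero(fr > 0))
    if len(uniq) < n_nonempty:
        raise ValueError(
            f"need at least {n_nonempty} distinct groups, got {len(uniq)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    sizes = _largest_remainder(len(uniq), fr)
    fold_of_group = {}
    start = 0
    for fold, size in zip(FOLDS, sizes):
        for gi in order[start:start + size]:
            fold_of_group[uniq[gi]] = fold
        start += size
    folds = np.asarray([fold_of_group[g] for g in groups], dtype=object)
    return SplitAssignment(folds, scheme=scheme_name, seed=seed,
                           fractions=tuple(fr), group_of=groups)


def split_by_inhibitor(table, seed: int,
                       fractions=DEFAULT_FRACTIONS) -> SplitAssignment:
    """Compound-held-out split: 10% of inhibitors to test, a disjoint 10% to
    validation, the rest to train; every measurement follows its inhibitor."""
    inhibitors = table.df["inhibitor_id"].to_numpy()
    if len(pd.unique(inhibitors)) < 10:
        raise ValueError("need at least 10 distinct inhibitors")
    return split_by_group(table, inhibitors, seed, fractions,
                          scheme_name="by_inhibitor")


def split_table(table, scheme: str, seed: int, fractions=DEFAULT_FRACTIONS,
                group_of=None) -> SplitAssignment:
    """Dispatch on scheme name ('standard', 'by_inhibitor', 'by_group')."""
    if scheme == "standard":
        return split_standard(table, seed, fractions)
    if scheme == "by_inhibitor":
        return split_by_inhibitor(table, seed, fractions)
    if scheme == "by_group":
        if group_of is None:
            raise ValueError("scheme 'by_group' requires a group map")
        return split_by_group(table, group_of, seed, fractions)
    raise ValueError(f"unknown scheme {scheme!r}")
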