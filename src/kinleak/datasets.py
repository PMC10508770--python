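"""Bioactivity table ingestion and label standardization.

All labels are brought onto a common "pActivity" scale: -log10 of a molar
potency (pIC50, pKd, or a source-provided pAct).  Single-dose percent
inhibition screens are converted to pIC50 under a Hill-slope-1 (single-site
competitive) binding model at the screening dose, after clipping the percent
scale to [2, 98] so the log transform stays finite.

The canonical table schema is one row per kinase-inhibitor measurement:

    kinase_id, klifs_sequence, inhibitor_id, smiles, label, label_type

where ``klifs_sequence`` is the 85-residue standardized ATP-pocket sequence
(gap character ``-`` for missing residues) and ``label`` is on the pActivity
scale after conversion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

KLIFS_LENGTH = 85
KLIFS_GAP = "-"
MAX_SMILES_LEN = 90
#: percent-inhibition clipping bounds: values outside are recorded at the bound
CLIP_LO, CLIP_HI = 2.0, 98.0
#: screening concentration (uM) assumed for single-dose percent-inhibition data
DEFAULT_DOSE_UM = 0.5

LABEL_TYPES = ("percent_inhibition", "Kd", "pKd", "pIC50", "pAct")

CANONICAL_COLUMNS = ["kinase_id", "klifs_sequence", "inhibitor_id", "smiles",
                     "label", "label_type"]


class SchemaError(ValueError):
    """Raised when an input table violates the canonical schema."""


@dataclass(frozen=True)
class BioactivityRecord:
    kinase_id: str
    klifs_sequence: str
    inhibitor_id: str
    smiles: str
    label: float
    label_type_original: str = "pAct"

    def __post_init__(self):
        if len(self.klifs_sequence) != KLIFS_LENGTH:
            raise ValueError(
                f"klifs_sequence must have length {KLIFS_LENGTH}, "
                f"got {len(self.klifs_sequence)}")
        if not (1 <= len(self.smiles) <= MAX_SMILES_LEN):
            raise ValueError("smiles length must be in [1, 90]")
        if not math.isfinite(self.label):
            raise ValueError("label must be finite")


@dataclass
class BioactivityTable:
    """Ordered collection of measurements backed by a pandas DataFrame."""

    df: pd.DataFrame
    name: str = "unnamed"

    def __post_init__(self):
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing canonical columns: {missing}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def kinase_ids(self):
        return self.df["kinase_id"].unique()

    @property
    def inhibitor_ids(self):
        return self.df["inhibitor_id"].unique()

    def smiles_of(self) -> dict:
        """inhibitor_id -> smiles (each inhibitor has exactly one)."""
        return dict(self.df.drop_duplicates("inhibitor_id")
                    [["inhibitor_id", "smiles"]].itertuples(index=False))

    def klifs_of(self) -> dict:
        return dict(self.df.drop_duplicates("kinase_id")
                    [["kinase_id", "klifs_sequence"]].itertuples(index=False))

    def validate_consistency(self) -> None:
        """Every inhibitor maps to one SMILES; every kinase to one KLIFS string."""
        if self.df.groupby("inhibitor_id")["smiles"].nunique().max() > 1:
            raise SchemaError("an inhibitor_id maps to more than one smiles")
        if self.df.groupby("kinase_id")["klifs_sequence"].nunique().max() > 1:
            raise SchemaError("a kinase_id maps to more than one klifs_sequence")

    def records(self):
        for row in self.df.itertuples(index=False):
            yield BioactivityRecord(row.kinase_id, row.klifs_sequence,
                                    row.inhibitor_id, row.smiles,
                                    float(row.label), row.label_type)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# label conversions
# ---------------------------------------------------------------------------

def clip_percent_inhibition(p: float) -> float:
    """Clip percent inhibition to [2, 98]: values above 98 are recorded as 98,
    values below 2 as 2."""
    if not (0.0 <= p <= 100.0):
        raise ValueError(f"percent inhibition must lie in [0, 100], got {p}")
    return min(max(float(p), CLIP_LO), CLIP_HI)


def percent_inhibition_to_pic50(p: float, dose_uM: float = DEFAULT_DOSE_UM,
                                formula: str = "hill") -> float:
    """Estimate pIC50 from single-dose percent inhibition.

    Under single-site competitive inhibition with Hill slope 1, the fractional
    inhibition f at dose D satisfies f = D / (D + IC50), hence
    IC50 = D * (1 - f) / f.  The dose is in micromolar; the IC50 is converted
    to molar before taking -log10.  Strictly increasing in p.

    ``formula="literal"`` selects the anti-monotone variant
    IC50 = D * f / (1 - f), kept only for comparison against sources that
    print the conversion that way.
    """
    if dose_uM <= 0:
        raise ValueError("dose must be positive")
    f = clip_percent_inhibition(p) / 100.0
    if formula == "hill":
        ic50_uM = dose_uM * (1.0 - f) / f
    elif formula == "literal":
        ic50_uM = dose_uM * f / (1.0 - f)
    else:
        raise ValueError(f"unknown formula {formula!r}")
    return -math.log10(ic50_uM * 1e-6)


def pic50_to_percent_inhibition(pic50: float, dose_uM: float = DEFAULT_DOSE_UM) -> float:
    """Algebraic inverse of :func:`percent_inhibition_to_pic50` (hill form);
    returns the clipped percent value."""
    ic50_uM = 10.0 ** (-pic50) * 1e6
    f = dose_uM / (dose_uM + ic50_uM)
    return 100.0 * f


def kd_to_pkd(kd_molar: float) -> float:
    """pKd = -log10(Kd) for a molar dissociation constant; Kd <= 0 is unphysical
    and rejected (such records are dropped by the readers)."""
    if kd_molar <= 0:
        raise ValueError("dissociation constant must be positive")
    return -math.log10(kd_molar)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterLog:
    dropped_long_smiles: int = 0
    dropped_bad_klifs: int = 0
    dropped_nonpositive_kd: int = 0
    dropped_malformed: int = 0
    notes: list = field(default_factory=list)

    @property
    def total_dropped(self) -> int:
        return (self.dropped_long_smiles + self.dropped_bad_klifs
                + self.dropped_nonpositive_kd + self.dropped_malformed)


def filter_table(table: BioactivityTable,
                 max_smiles_len: int = MAX_SMILES_LEN,
                 strict: bool = False) -> tuple[BioactivityTable, FilterLog]:
    """Apply the standard record filters.

    Retained records have SMILES of at most ``max_smiles_len`` characters
    (strict inequality drops only longer strings), a KLIFS sequence of exactly
    85 characters, and a finite label.  Idempotent: filtering a filtered table
    drops nothing.
    """
    df = table.df
    log = FilterLog()

    bad_label = ~np.isfinite(pd.to_numeric(df["label"], errors="coerce"))
    log.dropped_malformed = int(bad_label.sum())
    if strict and log.dropped_malformed:
        raise SchemaError(f"{log.dropped_malformed} records with non-finite labels")

    long_smiles = df["smiles"].astype(str).str.len() > max_smiles_len
    log.dropped_long_smiles = int((long_smiles & ~bad_label).sum())

    bad_klifs = df["klifs_sequence"].astype(str).str.len() != KLIFS_LENGTH
    log.dropped_bad_klifs = int((bad_klifs & ~long_smiles & ~bad_label).sum())

    keep = ~(bad_label | long_smiles | bad_klifs)
    out = BioactivityTable(df[keep].reset_index(drop=True), name=table.name)
    if log.total_dropped:
        logger.info("filter_table(%s): dropped %d records (%s)",
                    table.name, log.total_dropped, log)
    return out, log


# ---------------------------------------------------------------------------
# CSV reading
# ---------------------------------------------------------------------------

#: how a source label column is brought onto the pActivity scale
_UNIT_CONVERTERS = {
    "pAct": lambda v: v,
    "pKd": lambda v: v,
    "pIC50": lambda v: v,
    "Kd_M": kd_to_pkd,
    "Kd_nM": lambda v: kd_to_pkd(v * 1e-9),
    "Kd_uM": lambda v: kd_to_pkd(v * 1e-6),
    "percent_inhibition": percent_inhibition_to_pic50,
    "percent_activity": lambda v: percent_inhibition_to_pic50(100.0 - v),
}

_UNIT_TO_LABEL_TYPE = {
    "pAct": "pAct", "pKd": "pKd", "pIC50": "pIC50",
    "Kd_M": "Kd", "Kd_nM": "Kd", "Kd_uM": "Kd",
    "percent_inhibition": "percent_inhibition",
    "percent_activity": "percent_inhibition",
}


def read_bioactivity_csv(path, schema_config: dict | None = None,
                         name: str | None = None,
                         duplicates: str = "reject",
                         strict: bool = True) -> BioactivityTable:
    """Read a bioactivity CSV and standardize labels to the pActivity scale.

    ``schema_config`` maps canonical field names to source columns and
    declares the label unit::

        {"columns": {"kinase_id": "kinase", "label": "Kd (nM)", ...},
         "label_unit": "Kd_nM"}

    Omitted entries default to the canonical column names with unit "pAct".
    Percent-activity sources are converted to percent inhibition as
    100 - activity before the Hill-slope-1 conversion.  Records whose
    conversion fails (e.g. Kd <= 0) are dropped with a log message, or raise
    in strict duplicate/malformed situations as documented below.

    ``duplicates``: "reject" (default) raises on repeated
    (kinase_id, inhibitor_id) pairs; "mean" aggregates replicate labels by
    their mean; "keep" leaves them in place.
    """
    schema_config = schema_config or {}
    colmap = dict(schema_config.get("columns", {}))
    unit = schema_config.get("label_unit", "pAct")
    if unit not in _UNIT_CONVERTERS:
        raise SchemaError(f"unknown label unit {unit!r}; "
                          f"expected one of {sorted(_UNIT_CONVERTERS)}")
    convert = _UNIT_CONVERTERS[unit]

    raw = pd.read_csv(path, dtype=str)
    rename = {}
    for canonical in ["kinase_id", "klifs_sequence", "inhibitor_id", "smiles", "label"]:
        src = colmap.get(canonical, canonical)
        if src not in raw.columns:
            raise SchemaError(f"column {src!r} (for {canonical!r}) missing from {path}")
        rename[src] = canonical
    df = raw.rename(columns=rename)[["kinase_id", "klifs_sequence",
                                     "inhibitor_id", "smiles", "label"]].copy()

    values = pd.to_numeric(df["label"], errors="coerce")
    if values.isna().any():
        n = int(values.isna().sum())
        if strict:
            raise SchemaError(f"{n} unparseable label values in {path}")
        logger.warning("dropping %d unparseable labels from %s", n, path)
    df["original_value"] = values
    converted = []
    for v in values:
        if not np.isfinite(v):
            converted.append(np.nan)
            continue
        try:
            converted.append(convert(float(v)))
        except ValueError:
            converted.append(np.nan)  # e.g. nonpositive Kd: unphysical, drop
    df["label"] = converted
    df["label_type"] = _UNIT_TO_LABEL_TYPE[unit]
    df["applied_conversion"] = unit
    n_dropped = int(pd.isna(df["label"]).sum())
    if n_dropped:
        logger.info("read_bioactivity_csv(%s): dropped %d unconvertible records",
                    path, n_dropped)
    df = df.dropna(subset=["label"]).reset_index(drop=True)

    dup = df.duplicated(subset=["kinase_id", "inhibitor_id"], keep=False)
    if dup.any():
        if duplicates == "reject":
            pairs = df.loc[dup, ["kinase_id", "inhibitor_id"]].drop_duplicates()
            raise SchemaError(
                f"{len(pairs)} duplicated (kinase, inhibitor) pairs in {path}; "
                "pass duplicates='mean' to aggregate replicates")
        if duplicates == "mean":
            df = (df.groupby(["kinase_id", "inhibitor_id"], sort=False, as_index=False)
                  .agg({"klifs_sequence": "first", "smiles": "first",
                        "label": "mean", "label_type": "first",
                        "original_value": "mean", "applied_conversion": "first"}))
        elif duplicates != "keep":
            raise ValueError(f"unknown duplicates policy {duplicates!r}")

    table = BioactivityTable(df, name=name or str(path))
    table.validate_consistency()
    return table


def load_schema_config(path) -> dict:
    """Load a per-source schema adapter (YAML: ``label_unit`` plus optional
    ``columns`` mapping); see the configs/ directory for the shipped ones."""
    import yaml
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "label_unit" in raw and raw["label_unit"] not in _UNIT_CONVERTERS:
        raise SchemaError(f"unknown label unit {raw['label_unit']!r} in {path}")
    return raw


def write_standardized_csv(table: BioactivityTable, path) -> None:
    """Write the canonical schema plus provenance columns where present."""
    table.df.to_csv(path, index=False)
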