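"""The label-transfer (one-nearest-neighbor) baseline predictor.

For a query (inhibitor, kinase) pair, find the training-set inhibitor most
similar to the query inhibitor *among those measured against the query
kinase*, and repeat back its training label verbatim — no interpolation.  A
deep model that merely memorizes analog structure cannot beat this baseline,
which is what makes it the reference point of the leakage audit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .chemsim import SimilarityFunction
from .metrics import concordance_index, mse, pearson_r


@dataclass
class Prediction:
    label: float
    neighbor_id: str | None
    similarity: float
    fallback: bool = False


@dataclass
class LabelTransferModel:
    """1NN label transfer under a fixed inhibitor-similarity measure.

    Predictions are always labels that literally occur in the training table.
    Ties on similarity break to the lexicographically smallest inhibitor_id;
    a kinase with no training measurements at all falls back to the global
    training-label mean (flagged in the prediction's provenance).
    """

    similarity: SimilarityFunction
    _labels: dict = field(default_factory=dict, repr=False)     # (kinase, inhibitor) -> label
    _by_kinase: dict = field(default_factory=dict, repr=False)  # kinase -> sorted inhibitor ids
    _smiles: dict = field(default_factory=dict, repr=False)
    _global_mean: float = float("nan")
    _sim_cache: dict = field(default_factory=dict, repr=False)

    def fit(self, table, fit_similarity: bool = True) -> "LabelTransferModel":
        df = table.df
        if len(df) == 0:
            raise ValueError("cannot fit on an empty training table")
        self._smiles = table.smiles_of()
        self._labels = {}
        self._by_kinase = {}
        grouped = df.groupby("kinase_id")["inhibitor_id"]
        for kinase, inhibitors in grouped:
            self._by_kinase[kinase] = sorted(inhibitors.unique())
        for row in df.itertuples(index=False):
            self._labels[(row.kinase_id, row.inhibitor_id)] = float(row.label)
        self._global_mean = float(df["label"].mean())
        self._sim_cache = {}
        if fit_similarity and self.similarity.requires_fit:
            self.similarity.fit(list(self._smiles.values()))
        return self

    def _sim(self, query_smiles: str, train_inhibitor: str) -> float:
        key = (query_smiles, train_inhibitor)
        if key not in self._sim_cache:
            self._sim_cache[key] = self.similarity(
                query_smiles, self._smiles[train_inhibitor])
        return self._sim_cache[key]

    def predict_one(self, query_smiles: str, query_kinase: str) -> Prediction:
        candidates = self._by_kinase.get(query_kinase, [])
        if not candidates:
            return Prediction(self._global_mean, None, float("nan"),
                              fallback=True)
        best_id, best_sim = None, -1.0
        for inhib in candidates:  # sorted: ties keep the smallest id
            s = self._sim(query_smiles, inhib)
            if s > best_sim:
                best_id, best_sim = inhib, s
        return Prediction(self._labels[(query_kinase, best_id)],
                          best_id, best_sim)

    def predict(self, table) -> list[Prediction]:
        """Predict every record of a (test) table, in table order."""
        return [self.predict_one(row.smiles, row.kinase_id)
                for row in table.df.itertuples(index=False)]


def evaluate_label_transfer(train_table, test_table,
                            similarity: SimilarityFunction) -> dict:
    """Fit on the training fold, predict the test fold, return the metric row
    (CI, MSE, Pearson R, test size, fallback count)."""
    model = LabelTransferModel(similarity).fit(train_table)
    preds = model.predict(test_table)
    truth = test_table.df["label"].to_numpy(dtype=float)
    pred = np.array([p.label for p in preds])
    n_fallback = sum(p.fallback for p in preds)
    if n_fallback:
        warnings.warn(f"{n_fallback} test records used the global-mean fallback")
    return {"model": f"label_transfer:{similarity.name}",
            "ci": concordance_index(truth, pred),
            "mse": mse(truth, pred),
            "pearson_r": pearson_r(truth, pred),
            "n_test": int(len(truth)),
            "n_fallback": int(n_fallback)}
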