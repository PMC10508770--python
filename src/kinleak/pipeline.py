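"""End-to-end experiment orchestration for the leakage audit.

An :class:`ExperimentPlan` names a dataset (a table or a generator config),
the splitting schemes, the models and the seeds.  :func:`run_experiment`
executes every (scheme, model, seed) cell — split once per (scheme, seed),
share that assignment across all models, train/fit, predict the test fold,
score — and returns a Table-style report.  :func:`compare_models` reduces a
report to the leakage deltas the audit is about:

* ``standard - by_inhibitor`` (and ``- by_group``): how much apparent skill
  evaporates when compounds (or whole scaffolds) are held out;
* ``cnn_real - cnn_junk``: how much the CNN actually reads SMILES chemistry
  beyond the identity token;
* ``cnn - best 1NN``: whether the deep model beats copying the most similar
  training label.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import chemsim
from .affinity_cnn import CnnConfig, build_model, train as train_cnn
from .encoders import Vocabulary, encode_pairs, make_junk_smiles
from .metrics import ExperimentReport
from .nn_baseline import LabelTransferModel
from .metrics import concordance_index, mse as mse_metric, pearson_r
from .splits import split_table

logger = logging.getLogger(__name__)

#: per-stage substream labels, so any stage is independently reproducible
_STAGES = ("split", "junk", "generator", "model")


def stage_seed(plan_seed: int, stage: str, index: int = 0) -> int:
    """Derive a deterministic, stage-specific child seed (< 2**31)."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([plan_seed, _STAGES.index(stage), index])
    return int(ss.generate_state(1)[0]) % (2 ** 31)


@dataclass
class ExperimentPlan:
    table: object                      # BioactivityTable
    schemes: tuple = ("standard", "by_inhibitor")
    models: tuple = ("cnn_real",)      # cnn_real | cnn_junk | label_transfer:<measure>
    seeds: tuple = (0,)
    cnn_config: CnnConfig | None = None
    group_of: object = None            # record->group map for 'by_group'
    dataset_name: str | None = None
    backend: object = None             # StructureBackend for structural measures

    def __post_init__(self):
        for model in self.models:
            if model in ("cnn_real", "cnn_junk"):
                continue
            if model.startswith("label_transfer:"):
                measure = model.split(":", 1)[1]
                if measure not in chemsim.MEASURE_NAMES:
                    raise ValueError(f"unknown similarity measure {measure!r}")
                continue
            raise ValueError(f"unknown model {model!r}")


def _subset(table, indices):
    from .datasets import BioactivityTable
    return BioactivityTable(table.df.iloc[indices].reset_index(drop=True),
                            name=table.name)


def _encode_table(table, smiles_vocab, klifs_vocab, smiles_override=None):
    smiles = table.df["smiles"]
    if smiles_override is not None:
        smiles = table.df["inhibitor_id"].map(smiles_override)
    xs, xk = encode_pairs(smiles.tolist(),
                          table.df["klifs_sequence"].tolist(),
                          smiles_vocab, klifs_vocab)
    return xs, xk, table.df["label"].to_numpy(dtype=float)


def _run_cnn_cell(table, assignment, junk_map, cnn_config, model_seed):
    smiles_vocab = Vocabulary.smiles_default(table.df["smiles"].unique())
    klifs_vocab = Vocabulary.klifs_default()
    folds = {f: _subset(table, assignment.indices(f))
             for f in ("train", "validation", "test")}
    enc = {f: _encode_table(folds[f], smiles_vocab, klifs_vocab,
                            smiles_override=junk_map)
           for f in folds}
    cfg = cnn_config.with_(seed=model_seed)
    model = build_model(cfg, smiles_vocab.size, klifs_vocab.size)
    trained = train_cnn(model, enc["train"][:3], enc["validation"][:3], cfg)
    pred = trained.predict_batch(enc["test"][0], enc["test"][1])
    return enc["test"][2], np.asarray(pred, dtype=float), trained


def _run_label_transfer_cell(table, assignment, measure_name, backend):
    train_table = _subset(table, assignment.indices("train"))
    test_table = _subset(table, assignment.indices("test"))
    similarity = chemsim.get_similarity(measure_name, backend=backend)
    model = LabelTransferModel(similarity).fit(train_table)
    preds = model.predict(test_table)
    truth = test_table.df["label"].to_numpy(dtype=float)
    pred = np.array([p.label for p in preds])
    return truth, pred, model


def run_experiment(plan: ExperimentPlan, keep_predictions: bool = False):
    """Execute every (scheme, model, seed) cell of the plan.

    Returns (report, artifacts): the report has one row per cell; artifacts
    holds the split assignments (always) and per-record predictions (on
    request), keyed by (scheme, model, seed).
    """
    report = ExperimentReport()
    artifacts = {"splits": {}, "predictions": {}, "models": {}}
    dataset_name = plan.dataset_name or getattr(plan.table, "name", "dataset")
    cnn_config = plan.cnn_config or CnnConfig.desk()

    junk_map_by_seed = {}
    for seed in plan.seeds:
        for scheme in plan.schemes:
            assignment = split_table(plan.table, scheme,
                                     stage_seed(seed, "split"),
                                     group_of=plan.group_of)
            artifacts["splits"][(scheme, seed)] = assignment
            for model_name in plan.models:
                try:
                    if model_name in ("cnn_real", "cnn_junk"):
                        junk_map = None
                        if model_name == "cnn_junk":
                            if seed not in junk_map_by_seed:
                                junk_map_by_seed[seed] = make_junk_smiles(
                                    plan.table.smiles_of(),
                                    stage_seed(seed, "junk"))
                            junk_map = junk_map_by_seed[seed]
                        truth, pred, fitted = _run_cnn_cell(
                            plan.table, assignment, junk_map, cnn_config,
                            stage_seed(seed, "model"))
                    else:
                        measure = model_name.split(":", 1)[1]
                        truth, pred, fitted = _run_label_transfer_cell(
                            plan.table, assignment, measure, plan.backend)
                except Exception:
                    logger.exception("cell (%s, %s, seed=%d) failed; continuing",
                                     scheme, model_name, seed)
                    continue
                report.add(dataset_name, scheme, model_name, truth, pred, seed)
                if keep_predictions:
                    artifacts["predictions"][(scheme, model_name, seed)] = (truth, pred)
                    artifacts["models"][(scheme, model_name, seed)] = fitted
    return report, artifacts


def compare_models(report: ExperimentReport) -> dict:
    """Leakage summary: per-seed and mean CI deltas between schemes/models.

    Emits whichever of the three deltas the report supports, warning about
    the rest.
    """
    df = report.to_frame()
    out = {}

    def mean_ci(scheme=None, model=None, model_prefix=None):
        sel = df
        if scheme is not None:
            sel = sel[sel.scheme == scheme]
        if model is not None:
            sel = sel[sel.model == model]
        if model_prefix is not None:
            sel = sel[sel.model.str.startswith(model_prefix)]
        return sel

    # scheme gap for every model present under both schemes
    for model in df.model.unique():
        sub = df[df.model == model]
        schemes = set(sub.scheme)
        for held_out in ("by_inhibitor", "by_group"):
            if "standard" in schemes and held_out in schemes:
                a = sub[sub.scheme == "standard"].ci.mean()
                b = sub[sub.scheme == held_out].ci.mean()
                out[f"delta_ci_standard_minus_{held_out}:{model}"] = float(a - b)

    # real vs junk CNN under matched schemes
    real = mean_ci(model="cnn_real")
    junk = mean_ci(model="cnn_junk")
    common = set(real.scheme) & set(junk.scheme)
    if common:
        for scheme in sorted(common):
            a = real[real.scheme == scheme].ci.mean()
            b = junk[junk.scheme == scheme].ci.mean()
            out[f"delta_ci_real_minus_junk:{scheme}"] = float(a - b)
    elif len(junk) == 0 and len(real) > 0:
        warnings.warn("report lacks cnn_junk cells; junk delta not emitted")

    # CNN vs best label-transfer measure, per scheme
    lt = mean_ci(model_prefix="label_transfer:")
    for scheme in sorted(set(df.scheme)):
        cnn_rows = real[real.scheme == scheme]
        lt_rows = lt[lt.scheme == scheme]
        if len(cnn_rows) and len(lt_rows):
            best = lt_rows.groupby("model").ci.mean().max()
            out[f"delta_ci_cnn_minus_best_1nn:{scheme}"] = float(
                cnn_rows.ci.mean() - best)
    return out
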