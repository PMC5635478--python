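"""Bag-level cross-validation, metrics, and the experiment runner.

Evaluation is at the entity (bag) level: folds partition *bags*, never
instances, so a (drug, event) pair can never leak across folds.  Folds
are stratified by label and deterministic given the seed.  Metrics use
ADR as the positive class:

    precision = tp / (tp + fp)     recall = tp / (tp + fn)
    F1 = 2 P R / (P + R)           accuracy = (tp + tn) / total

with the convention that a denominator of zero yields 0.
In transductive modes the held-out test fold plays the role of the
unlabeled set D_U during training.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from sklearn.model_selection import StratifiedKFold

from .corpus import ADR, Bag
from .features import FeatureConfig
from .mil import BagPrediction, TrainConfig, train
from .supervision import LabeledCorpus


@dataclass
class MetricsReport:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    accuracy: float

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def compute_metrics(
    predictions: Sequence[BagPrediction] | Mapping[str, str],
    truth: Mapping[str, str],
) -> MetricsReport:
    """Confusion counts and the three headline metrics, ADR positive."""
    if not isinstance(predictions, Mapping):
        predictions = {p.bag_id: p.label for p in predictions}
    missing = set(truth) - set(predictions)
    if missing:
        raise ValueError(f"missing predictions for bags {sorted(missing)[:5]}")
    tp = fp = fn = tn = 0
    for bag_id, true_label in truth.items():
        pred = predictions[bag_id]
        if pred == ADR:
            tp += true_label == ADR
            fp += true_label != ADR
        else:
            fn += true_label == ADR
            tn += true_label != ADR
    if tp + fp == 0:
        warnings.warn("no predicted positives; precision reported as 0", stacklevel=2)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    accuracy = (tp + tn) / len(truth) if truth else 0.0
    return MetricsReport(tp, fp, fn, tn, precision, recall, f1, accuracy)


def kfold_split(
    bags: Sequence[Bag], k: int, seed: int
) -> list[tuple[list[str], list[str]]]:
    """Stratified bag-level folds as (train ids, test ids) pairs."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(bags) < k:
        raise ValueError(f"need at least {k} labeled bags for {k} folds")
    bags = sorted(bags, key=lambda b: b.bag_id)
    ids = np.array([b.bag_id for b in bags])
    labels = np.array([b.label for b in bags])
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (ids[tr].tolist(), ids[te].tolist())
        for tr, te in splitter.split(ids, labels)
    ]


@dataclass
class CVReport:
    folds: list[MetricsReport]
    mean_precision: float
    mean_recall: float
    mean_f1: float
    mean_accuracy: float

    def as_dict(self) -> dict:
        return {
            "folds": [f.as_dict() for f in self.folds],
            "mean": {
                "precision": self.mean_precision,
                "recall": self.mean_recall,
                "f1": self.mean_f1,
                "accuracy": self.mean_accuracy,
            },
        }


def _strip_label(bag: Bag) -> Bag:
    return Bag(bag.bag_id, bag.drug_cui, bag.event_cui, bag.tuple_ids, None)


def cross_validate(
    corpus: LabeledCorpus,
    feat_cfg: FeatureConfig,
    train_cfg: TrainConfig,
    k: int = 5,
    seed: int = 0,
    collect_predictions: list | None = None,
) -> CVReport:
    """k-fold CV over the labeled bags.

    Each fold trains on the remaining labeled bags; the test fold,
    labels hidden, serves as D_U (it is what the trained model scores,
    and in transductive modes it also joins the EM).  Genuinely
    unlabeled bags of ``corpus`` are not evaluated.
    """
    by_id = {b.bag_id: b for b in corpus.labeled_bags}
    reports = []
    for train_ids, test_ids in kfold_split(corpus.labeled_bags, k, seed):
        fold_corpus = LabeledCorpus(
            [by_id[i] for i in train_ids],
            [_strip_label(by_id[i]) for i in test_ids],
            corpus.tuples,
        )
        result = train(fold_corpus, feat_cfg, train_cfg)
        truth = {i: by_id[i].label for i in test_ids}
        reports.append(compute_metrics(result.predictions, truth))
        if collect_predictions is not None:
            collect_predictions.extend(result.predictions)
    return CVReport(
        reports,
        float(np.mean([r.precision for r in reports])),
        float(np.mean([r.recall for r in reports])),
        float(np.mean([r.f1 for r in reports])),
        float(np.mean([r.accuracy for r in reports])),
    )


_CONFIG_KEYS = {"data", "features", "training", "k", "seed", "out_dir"}


def run_experiment(config: str | Path | dict, out_dir: str | Path | None = None) -> CVReport:
    """Run a cross-validated experiment from a YAML config.

    Config schema::

        data:
          tuples: path/to/tuples.jsonl     # or `synthetic:` with
          seeds: path/to/seeds.tsv         # SynthConfig fields
        features: {lex_form: L, granularity: P, weighting: B}
        training: {model: iem, mode: sl, decision: soft, ...}
        k: 5
        seed: 0

    Writes ``report.json``, ``report.tsv`` and ``predictions.jsonl``
    to ``out_dir`` when given.
    """
    if not isinstance(config, dict):
        with open(config, encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    unknown = set(config) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}")
    if "data" not in config:
        raise ValueError("config requires a 'data' section")

    data_cfg = config["data"]
    seed = int(config.get("seed", 0))
    if "synthetic" in data_cfg:
        from .simulate import SynthConfig, generate

        synth = SynthConfig(**{"seed": seed, **data_cfg["synthetic"]})
        tuples, seeds, _ = generate(synth)
    else:
        from .corpus import read_seed_kb, read_tuples

        tuples = read_tuples(data_cfg["tuples"])
        seeds = read_seed_kb(data_cfg["seeds"])

    from .corpus import filter_candidate_tuples
    from .supervision import filter_ambiguous_seeds, label_corpus

    corpus = label_corpus(filter_candidate_tuples(tuples), filter_ambiguous_seeds(seeds))
    feat_cfg = FeatureConfig(**config.get("features", {}))
    train_cfg = TrainConfig(**{"seed": seed, **config.get("training", {})})
    k = int(config.get("k", 5))

    predictions: list[BagPrediction] = []
    report = cross_validate(corpus, feat_cfg, train_cfg, k, seed, predictions)

    out_dir = out_dir or config.get("out_dir")
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report.as_dict(), fh, indent=2)
        with open(out / "report.tsv", "w", encoding="utf-8") as fh:
            cols = ["fold", "tp", "fp", "fn", "tn", "precision", "recall", "f1", "accuracy"]
            fh.write("\t".join(cols) + "\n")
            for i, r in enumerate(report.folds):
                fh.write(
                    f"{i}\t{r.tp}\t{r.fp}\t{r.fn}\t{r.tn}"
                    f"\t{r.precision:.4f}\t{r.recall:.4f}\t{r.f1:.4f}\t{r.accuracy:.4f}\n"
                )
            fh.write(
                f"mean\t\t\t\t\t{report.mean_precision:.4f}\t{report.mean_recall:.4f}"
                f"\t{report.mean_f1:.4f}\t{report.mean_accuracy:.4f}\n"
            )
        with open(out / "predictions.jsonl", "w", encoding="utf-8") as fh:
            for p in predictions:
                fh.write(
                    json.dumps(
                        {
                            "bag_id": p.bag_id,
                            "scores": [float(s) for s in p.scores],
                            "label": p.label,
                            "witness": p.witness,
                        }
                    )
                    + "\n"
                )
    return report
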