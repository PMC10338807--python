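"""Classification metrics, cross-validation designs and per-nodule
aggregation of panel predictions.

Metrics (malignant = positive class): accuracy, sensitivity/recall,
specificity, precision and F1.  Two split designs are provided: stratified
five-fold cross-validation at nodule level (panel-label experiments) and a
four-subset design (two train / one validation / one test, roles rotated)
for individual-label experiments.  All annotations of one nodule always
stay in one fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "precision": self.precision,
                "f1": self.f1}


def confusion(predicted, truth) -> ConfusionCounts:
    predicted = list(predicted)
    truth = list(truth)
    if len(predicted) != len(truth):
        raise ValueError(
            f"{len(predicted)} predictions vs {len(truth)} truths")
    for v in (*predicted, *truth):
        if v not in (0, 1):
            raise ValueError(f"classes must be 0/1, got {v!r}")
    tp = sum(p == 1 and t == 1 for p, t in zip(predicted, truth))
    tn = sum(p == 0 and t == 0 for p, t in zip(predicted, truth))
    fp = sum(p == 1 and t == 0 for p, t in zip(predicted, truth))
    fn = sum(p == 0 and t == 1 for p, t in zip(predicted, truth))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num, den, name):
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator)")
        return float("nan")
    return num / den


def metrics(c: ConfusionCounts) -> MetricSet:
    if c.total == 0:
        raise ValueError("metrics require at least one case")
    sens = _ratio(c.tp, c.tp + c.fn, "sensitivity")
    spec = _ratio(c.tn, c.tn + c.fp, "specificity")
    prec = _ratio(c.tp, c.tp + c.fp, "precision")
    if np.isnan(prec) or np.isnan(sens) or prec + sens == 0:
        f1 = float("nan")
        warnings.warn("f1 undefined")
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return MetricSet(accuracy=(c.tp + c.tn) / c.total, sensitivity=sens,
                     specificity=spec, precision=prec, f1=f1)


def metrics_to_csv(fold_metrics: list[MetricSet], path) -> None:
    """One row per fold plus a mean and a standard-deviation summary row."""
    import csv

    keys = ("accuracy", "sensitivity", "specificity", "precision", "f1")
    summary = summarize_folds(fold_metrics)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(("fold",) + keys)
        for i, m in enumerate(fold_metrics):
            writer.writerow([i] + [f"{getattr(m, k):.6f}" for k in keys])
        writer.writerow(["mean"] + [f"{summary[k]['mean']:.6f}"
                                    for k in keys])
        writer.writerow(["std"] + [f"{summary[k]['std']:.6f}" for k in keys])


def summarize_folds(fold_metrics: list[MetricSet]) -> dict:
    """Sample mean and standard deviation of each metric across folds."""
    out = {}
    for key in ("accuracy", "sensitivity", "specificity", "precision", "f1"):
        vals = np.array([getattr(m, key) for m in fold_metrics])
        out[key] = {"mean": float(vals.mean()),
                    "std": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0}
    return out


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def make_folds(cases, scheme: str, seed: int = 0):
    """Assign nodule-level folds.

    ``cases`` is a sequence of ``(nodule_id, label)`` pairs; annotations
    sharing a nodule id always land in the same fold.

    * ``panel_5fold``: 5 stratified folds; returns a list of
      ``(train_ids, test_ids)`` tuples.
    * ``individual_4subset``: 4 stratified subsets with roles
      train/train/validation/test rotated; returns a list of 4 dicts with
      ``train``/``val``/``test`` id lists.
    """
    nodule_labels: dict = {}
    for nid, label in cases:
        prev = nodule_labels.setdefault(nid, label)
        if prev != label:
            raise ValueError(f"conflicting labels for nodule {nid}")
    ids = np.array(sorted(nodule_labels))
    labels = np.array([nodule_labels[n] for n in ids])
    if scheme == "panel_5fold":
        k = 5
    elif scheme == "individual_4subset":
        k = 4
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if len(ids) < k:
        raise ValueError(f"{len(ids)} nodules is fewer than {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    subsets = [ids[test] for _, test in skf.split(ids, labels)]
    if scheme == "panel_5fold":
        return [
            (np.concatenate([s for j, s in enumerate(subsets) if j != i])
             .tolist(), subsets[i].tolist())
            for i in range(5)
        ]
    rotations = []
    for i in range(4):
        order = [(i + j) % 4 for j in range(4)]
        rotations.append({
            "train": np.concatenate([subsets[order[0]],
                                     subsets[order[1]]]).tolist(),
            "val": subsets[order[2]].tolist(),
            "test": subsets[order[3]].tolist(),
        })
    return rotations


# ---------------------------------------------------------------------------
# per-nodule aggregation
# ---------------------------------------------------------------------------

def aggregate_panel_predictions(per_annotation_probs, nodule_ids):
    """Mean of the refined panel head's probability vectors per nodule.

    Returns ``{nodule_id: (probability vector, argmax class)}``; the
    aggregation is permutation invariant in the annotations.
    """
    groups: dict = {}
    for p, nid in zip(per_annotation_probs, nodule_ids):
        groups.setdefault(nid, []).append(np.asarray(p, dtype=np.float64))
    out = {}
    for nid, probs in groups.items():
        mean = np.mean(probs, axis=0)
        out[nid] = (mean, int(np.argmax(mean)))
    return out
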