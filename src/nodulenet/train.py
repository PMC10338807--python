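"""Two-stage optimisation schedule.

Stage one (epochs 1..40 by default, learning rate 0.01) trains the backbone
and the ten prediction heads only, with the refinement branches frozen and
their loss excluded.  Stage two (epochs 41..80, learning rate 0.0001) trains
everything jointly, adding the collaborative loss on the two refined heads.
SGD with momentum 0.9, batch size 8, Xavier-initialised weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import nn
from .augment import AugmentConfig, augment_pair
from .data import Sample
from .losses import LossConfig, batch_loss_and_grads
from .network import NoduleNet
from .preprocess import ROIPair


@dataclass
class TrainConfig:
    stage1_epochs: int = 40
    total_epochs: int = 80
    lr_stage1: float = 0.01
    lr_stage2: float = 0.0001
    batch_size: int = 8
    momentum: float = 0.9
    weight_decay: float = 0.0
    select_head: str = "panel"     # head whose validation accuracy picks the checkpoint
    seed: int = 0

    def validate(self):
        if self.stage1_epochs >= self.total_epochs:
            raise ValueError("stage-1 epochs must be below the total")
        if self.lr_stage1 <= 0 or self.lr_stage2 <= 0:
            raise ValueError("learning rates must be positive")
        return self


def stage_of(epoch: int, cfg: TrainConfig) -> tuple[str, float]:
    """Map a 1-based epoch to (stage, learning rate)."""
    cfg.validate()
    if not 1 <= epoch <= cfg.total_epochs:
        raise ValueError(
            f"epoch {epoch} outside 1..{cfg.total_epochs}")
    if epoch <= cfg.stage1_epochs:
        return "fdid_only", cfg.lr_stage1
    return "joint", cfg.lr_stage2


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------

def _walk_layers(obj):
    if isinstance(obj, nn.Module):
        yield obj
        for v in vars(obj).values():
            yield from _walk_layers(v)
    elif isinstance(obj, (list, tuple)):
        for item in obj:
            yield from _walk_layers(item)


def init_weights(model: nn.Module, seed: int) -> nn.Module:
    """Re-initialise in place: Xavier-uniform conv/FC weights, zero biases,
    unit batch-norm scales and zero shifts.  Deterministic per seed."""
    rng = np.random.default_rng(seed)
    for layer in _walk_layers(model):
        if isinstance(layer, nn.Conv3d):
            g = layer.groups
            fi = (layer.cin // g) * layer.k ** 3
            fo = (layer.cout // g) * layer.k ** 3
            layer.weight.value[...] = nn.xavier_uniform(
                layer.weight.shape, fi, fo, rng)
            if layer.bias is not None:
                layer.bias.value[...] = 0.0
        elif isinstance(layer, nn.Linear):
            layer.weight.value[...] = nn.xavier_uniform(
                layer.weight.shape, layer.cin, layer.cout, rng)
            if layer.bias is not None:
                layer.bias.value[...] = 0.0
        elif isinstance(layer, (nn.BatchNorm1d, nn.BatchNorm3d)):
            layer.gamma.value[...] = 1.0
            layer.beta.value[...] = 0.0
            layer.running_mean[...] = 0.0
            layer.running_var[...] = 1.0
        elif isinstance(layer, nn.Dropout):
            layer.rng = np.random.default_rng(rng.integers(2**31))
    return model


# ---------------------------------------------------------------------------
# evaluation-mode inference
# ---------------------------------------------------------------------------

def predict_samples(model: NoduleNet, samples: list[Sample],
                    batch_size: int = 8):
    """Evaluation-mode forward over a sample list; returns a list of dicts
    with the four diagnosis probability vectors per sample."""
    out = []
    for start in range(0, len(samples), batch_size):
        chunk = samples[start:start + batch_size]
        x = np.stack([s.stacked() for s in chunk])
        fdid, dr = model.forward(x, train=False)
        for i, s in enumerate(chunk):
            out.append({
                "nodule_id": s.nodule_id, "reader_id": s.reader_id,
                "individual": fdid.individual[i],
                "panel": fdid.panel[i],
                "refined_individual": dr.individual_refined[i],
                "refined_panel": dr.panel_refined[i],
                "semantic": {f: fdid.semantic[f][i]
                             for f in fdid.semantic},
            })
    return out


def _head_accuracy(preds, samples, head: str, label: str) -> float:
    correct = sum(
        int(np.argmax(p[head])) == s.labels[label]
        for p, s in zip(preds, samples))
    return correct / max(len(samples), 1)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def train_run(train_samples: list[Sample], val_samples: list[Sample],
              model: NoduleNet, cfg: TrainConfig,
              loss_cfg: LossConfig | None = None,
              augment_cfg: AugmentConfig | None = None,
              epoch_callback=None):
    """Execute the two-stage schedule; returns (model, per-epoch log).

    Panel-excluded samples are dropped up front.  The model state with the
    best validation accuracy on the selected refined head is restored at the
    end (stage-2 epochs only, since the refinement branches are untrained
    before that).
    """
    cfg.validate()
    loss_cfg = loss_cfg or LossConfig()
    train_samples = [s for s in train_samples if s.labels["panel"] in (0, 1)]
    val_samples = [s for s in val_samples if s.labels["panel"] in (0, 1)]
    if not train_samples:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    log: list[dict] = []
    best = (-1.0, None)
    optimizer = None
    current = (None, None)
    sel_head = f"refined_{cfg.select_head}"
    for epoch in range(1, cfg.total_epochs + 1):
        stage, lr = stage_of(epoch, cfg)
        if (stage, lr) != current:
            params = list(model.parameters()) if stage == "joint" \
                else list(model.fdid_parameters())
            optimizer = nn.SGD(params, lr=lr, momentum=cfg.momentum,
                               weight_decay=cfg.weight_decay)
            current = (stage, lr)
        step_cfg = replace(loss_cfg, stage=stage)
        order = rng.permutation(len(train_samples))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            batch = [train_samples[i] for i in order[start:start
                                                     + cfg.batch_size]]
            cubes, masks, labels = [], [], []
            for s in batch:
                pair = ROIPair(s.nodule_cube, s.mask_cube)
                if augment_cfg is not None:
                    pair = augment_pair(pair, augment_cfg, rng)
                cubes.append(pair.nodule_cube)
                masks.append(pair.mask_cube)
                labels.append(s.labels)
            x = np.stack([np.stack([c, m]) for c, m in zip(cubes, masks)])
            x = x.astype(np.float32)
            fdid, dr = model.forward(x, train=True)
            loss, head_grads, dr_grads = batch_loss_and_grads(
                fdid, dr if stage == "joint" else None, labels, step_cfg)
            optimizer.zero_grad()
            model.backward(head_grads, dr_grads)
            optimizer.step()
            epoch_loss += loss
            n_batches += 1
        entry = {"epoch": epoch, "stage": stage, "lr": lr,
                 "train_loss": epoch_loss / max(n_batches, 1)}
        if val_samples:
            preds = predict_samples(model, val_samples, cfg.batch_size)
            entry["val_acc_individual"] = _head_accuracy(
                preds, val_samples, "refined_individual", "individual")
            entry["val_acc_panel"] = _head_accuracy(
                preds, val_samples, "refined_panel", "panel")
            entry["val_acc_fdid_individual"] = _head_accuracy(
                preds, val_samples, "individual", "individual")
            entry["val_acc_fdid_panel"] = _head_accuracy(
                preds, val_samples, "panel", "panel")
            sel = entry[f"val_acc_{cfg.select_head}"]
            # ties go to the later epoch (the most-trained equal model)
            if stage == "joint" and sel >= best[0]:
                best = (sel, _snapshot(model))
        log.append(entry)
        if epoch_callback is not None:
            epoch_callback(epoch, stage, model)
    if best[1] is not None:
        _restore(model, best[1])
    return model, log


def _snapshot(model):
    params = {n: p.value.copy() for n, p in model.parameters()}
    state = {n: a.copy() for n, a in model.state_arrays()}
    return params, state


def _restore(model, snap):
    params, state = snap
    for n, p in model.parameters():
        p.value[...] = params[n]
    for n, a in model.state_arrays():
        a[...] = state[n]


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: NoduleNet, path: str | Path,
                    extra: dict | None = None):
    """Parameters + running statistics in an ``.npz``, with a JSON
    architecture descriptor alongside."""
    path = Path(path)
    arrays = {f"param/{n}": p.value for n, p in model.parameters()}
    arrays.update({f"state/{n}": a for n, a in model.state_arrays()})
    np.savez(path, **arrays)
    desc = {"backbone": model.backbone.config.to_dict()}
    if extra:
        desc.update(extra)
    path.with_suffix(".json").write_text(json.dumps(desc, indent=1))


def load_checkpoint(model: NoduleNet, path: str | Path) -> NoduleNet:
    data = np.load(Path(path).with_suffix(".npz"))
    for n, p in model.parameters():
        p.value[...] = data[f"param/{n}"]
    for n, a in model.state_arrays():
        a[...] = data[f"state/{n}"]
    return model
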