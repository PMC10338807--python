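"""Two-stage multi-task diagnosis network.

Stage one couples the shared 3D backbone with ten parallel prediction heads:
eight binary semantic-feature heads (subtlety, internal structure,
calcification, sphericity, margin, lobulation, spiculation, texture), an
*individual* diagnosis head supervised by the annotating reader's own label,
and a *panel* diagnosis head supervised by the reader panel's consensus
label.  Stage two (diagnosis refinement) concatenates the ten 2-d
probability vectors into a 20-d fusion feature and maps it through two small
fully connected branches to refined individual and panel diagnoses.

Class convention everywhere: index 0 = benign, index 1 = malignant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .backbone import Backbone, BackboneConfig, default_config
from .nn import (
    BatchNorm1d,
    Dropout,
    Linear,
    Module,
    ReLU,
    Sequential,
    Softmax,
)

#: canonical semantic-feature order; fusion and label vectors follow it.
SEMANTIC_FEATURES = (
    "subtlety", "internalStructure", "calcification", "sphericity",
    "margin", "lobulation", "spiculation", "texture",
)

BENIGN, MALIGNANT = 0, 1


@dataclass
class FDIDOutput:
    """Ten 2-d probability vectors from the first stage (rows = batch)."""
    semantic: dict[str, np.ndarray]
    individual: np.ndarray
    panel: np.ndarray

    def vectors(self) -> list[np.ndarray]:
        return [self.semantic[f] for f in SEMANTIC_FEATURES] + [
            self.individual, self.panel]


@dataclass
class DROutput:
    individual_refined: np.ndarray
    panel_refined: np.ndarray


class PredictionHead(Module):
    """FC(shared->hidden) -> BN -> ReLU -> Dropout(0.5) -> FC(hidden->2) -> softmax."""

    def __init__(self, shared_dim=1024, hidden=256, dropout=0.5,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.net = Sequential(
            Linear(shared_dim, hidden, rng=rng),
            BatchNorm1d(hidden), ReLU(), Dropout(dropout, rng=rng),
            Linear(hidden, 2, rng=rng), Softmax())

    def forward(self, shared, train: bool = False):
        if shared.ndim == 1:
            shared = shared[None]
        if shared.shape[-1] != self.net.layers[0].cin:
            raise ValueError(
                f"expected {self.net.layers[0].cin}-d shared feature, got "
                f"{shared.shape}")
        return self.net.forward(shared, train=train)

    def backward(self, gy):
        return self.net.backward(gy)


class RefinementBranch(Module):
    """FC(20->H) -> BN -> ReLU -> FC(H->2) -> softmax."""

    def __init__(self, hidden=32, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.net = Sequential(
            Linear(20, hidden, rng=rng), BatchNorm1d(hidden), ReLU(),
            Linear(hidden, 2, rng=rng), Softmax())

    def forward(self, fusion, train: bool = False):
        if fusion.shape[-1] != 20:
            raise ValueError(f"expected 20-d fusion vector, got {fusion.shape}")
        return self.net.forward(fusion, train=train)

    def backward(self, gy):
        return self.net.backward(gy)


def fuse_predictions(out: FDIDOutput) -> np.ndarray:
    """Concatenate the ten stage-one probability vectors into a 20-d fusion
    feature: eight semantic vectors in canonical order, then individual,
    then panel."""
    return np.concatenate(out.vectors(), axis=-1)


class NoduleNet(Module):
    """Backbone + ten prediction heads + two refinement branches."""

    def __init__(self, config: BackboneConfig | None = None,
                 head_hidden: int = 256, dr_hidden: int = 32,
                 dropout: float = 0.5,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        config = config or default_config()
        self.backbone = Backbone(config, rng=rng)
        sd = config.shared_dim
        self.heads = [PredictionHead(sd, head_hidden, dropout, rng=rng)
                      for _ in range(len(SEMANTIC_FEATURES) + 2)]
        self.dr_individual = RefinementBranch(dr_hidden, rng=rng)
        self.dr_panel = RefinementBranch(dr_hidden, rng=rng)

    # --- parameter partitions used by the two-stage schedule ---
    def fdid_parameters(self):
        for name, p in self.backbone.parameters():
            yield f"backbone.{name}", p
        for i, head in enumerate(self.heads):
            for name, p in head.parameters():
                yield f"heads.{i}.{name}", p

    def dr_parameters(self):
        for name, p in self.dr_individual.parameters():
            yield f"dr_individual.{name}", p
        for name, p in self.dr_panel.parameters():
            yield f"dr_panel.{name}", p

    def parameters(self):
        yield from self.fdid_parameters()
        yield from self.dr_parameters()

    # --- forward passes ---
    @staticmethod
    def _stack_input(nodule_cube, mask_cube):
        nodule_cube = np.asarray(nodule_cube)
        mask_cube = np.asarray(mask_cube)
        if nodule_cube.ndim == 3:
            nodule_cube = nodule_cube[None]
            mask_cube = mask_cube[None]
        if nodule_cube.shape != mask_cube.shape:
            raise ValueError("nodule and mask cubes must share a shape")
        vals = np.unique(mask_cube)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask cube must be strictly binary")
        return np.stack([nodule_cube, mask_cube], axis=1).astype(np.float32)

    def fdid_forward(self, nodule_cube, mask_cube,
                     train: bool = False) -> FDIDOutput:
        x = self._stack_input(nodule_cube, mask_cube)
        shared = self.backbone.forward(x, train=train)
        outs = [h.forward(shared, train=train) for h in self.heads]
        return FDIDOutput(
            semantic=dict(zip(SEMANTIC_FEATURES, outs[:8])),
            individual=outs[8], panel=outs[9])

    def dr_forward(self, fusion: np.ndarray, train: bool = False) -> DROutput:
        return DROutput(
            individual_refined=self.dr_individual.forward(fusion, train=train),
            panel_refined=self.dr_panel.forward(fusion, train=train))

    def forward(self, nodule_cube, mask_cube=None, train: bool = False):
        if mask_cube is None:  # allow pre-stacked (N,2,D,H,W) input
            x = np.asarray(nodule_cube, dtype=np.float32)
            nodule_cube, mask_cube = x[:, 0], x[:, 1]
        fdid = self.fdid_forward(nodule_cube, mask_cube, train=train)
        dr = self.dr_forward(fuse_predictions(fdid), train=train)
        return fdid, dr

    def backward(self, head_grads: list[np.ndarray],
                 dr_grads: tuple[np.ndarray, np.ndarray] | None = None):
        """Backpropagate gradients w.r.t. the 10 head outputs (canonical
        order) and optionally the two refinement outputs.

        Refinement gradients flow through the fusion vector back into the
        heads (no detachment), then everything flows into the backbone.
        """
        head_grads = [np.asarray(g, dtype=np.float32) for g in head_grads]
        if dr_grads is not None:
            gfus = (self.dr_individual.backward(dr_grads[0])
                    + self.dr_panel.backward(dr_grads[1]))
            for i in range(10):
                head_grads[i] = head_grads[i] + gfus[:, 2 * i:2 * i + 2]
        gshared = sum(h.backward(g) for h, g in zip(self.heads, head_grads))
        return self.backbone.backward(gshared)


def predictions_to_json(fdid: FDIDOutput, dr: DROutput, index: int = 0) -> str:
    """Serialize one case's 12 probability vectors."""
    rec = {
        "semantic": {f: fdid.semantic[f][index].tolist()
                     for f in SEMANTIC_FEATURES},
        "individual": fdid.individual[index].tolist(),
        "panel": fdid.panel[index].tolist(),
        "refined_individual": dr.individual_refined[index].tolist(),
        "refined_panel": dr.panel_refined[index].tolist(),
    }
    return json.dumps(rec)
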