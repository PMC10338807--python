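"""Collaborative soft-label loss and the stage-dependent training objective.

When several radiologists rate the same nodule, the label a given reader
assigns (the *individual* label y0) can contradict the panel consensus
(the *panel* label y1).  Instead of one-hot cross-entropy against y0 alone,
the target is softened,

    q'(k) = (1 - eps) * onehot(y0)[k] + eps * onehot(y1)[k],

and the collaborative loss is the cross-entropy of the prediction p against
q', which decomposes exactly as

    L_cb(q', p) = (1 - eps) * H(onehot(y0), p) + eps * H(onehot(y1), p).

With eps = 0 this is ordinary cross-entropy against the individual label;
eps defaults to 0.6.  When the two labels agree the soft target is one-hot
([1, 0] for benign/benign); when the reader says benign but the panel says
malignant it is [0.4, 0.6] at the default eps.  The panel head is supervised
symmetrically, with the roles of the two labels swapped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import SEMANTIC_FEATURES, DROutput, FDIDOutput

#: probability floor applied before taking logarithms
PROB_FLOOR = 1e-12

K = 2  # benign / malignant


@dataclass(frozen=True)
class SoftLabel:
    """Softened two-class target q' = (1-eps)*onehot(y0) + eps*onehot(y1)."""
    q: np.ndarray
    y0: int
    y1: int
    epsilon: float


@dataclass
class LossConfig:
    epsilon: float = 0.6            # weight of the panel label in q'
    epsilon_panel: float = 0.4      # weight of the individual label for the
    # panel head: the smoothing weight always attaches to the panel opinion,
    # so the panel head keeps 0.6 on its own label and 0.4 on the reference
    semantic_weight: float = 1.0
    stage: str = "fdid_only"        # or "joint"

    def validate(self):
        for e in (self.epsilon, self.epsilon_panel):
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"epsilon must lie in [0, 1], got {e}")
        if self.stage not in ("fdid_only", "joint"):
            raise ValueError(f"unknown stage {self.stage!r}")


def _onehot(y: int) -> np.ndarray:
    if y not in (0, 1):
        raise ValueError(f"class must be 0 (benign) or 1 (malignant), got {y}")
    v = np.zeros(K)
    v[y] = 1.0
    return v


def soften(y0: int, y1: int, epsilon: float) -> SoftLabel:
    """Build the softened target from individual label y0 and panel label y1."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError(f"epsilon must lie in [0, 1], got {epsilon}")
    q = (1.0 - epsilon) * _onehot(y0) + epsilon * _onehot(y1)
    return SoftLabel(q=q, y0=y0, y1=y1, epsilon=epsilon)


def cross_entropy(q: np.ndarray, p: np.ndarray) -> float:
    """H(q, p) = -sum_k q_k log p_k, natural log, p floored at PROB_FLOOR."""
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if abs(p.sum() - 1.0) > 1e-4 or np.any(p < -1e-6):
        raise ValueError(f"prediction {p} is not on the probability simplex")
    return float(-(q * np.log(np.maximum(p, PROB_FLOOR))).sum())


def collaborative_loss(p: np.ndarray, y0: int, y1: int,
                       epsilon: float) -> float:
    """Cross-entropy of p against the softened target of (y0, y1)."""
    return cross_entropy(soften(y0, y1, epsilon).q, p)


def collaborative_loss_grad(p: np.ndarray, y0: int, y1: int,
                            epsilon: float) -> np.ndarray:
    """d L_cb / d p  (gradient w.r.t. the probability vector)."""
    q = soften(y0, y1, epsilon).q
    p = np.asarray(p, dtype=np.float64)
    return (-q / np.maximum(p, PROB_FLOOR)).astype(np.float32)


def semantic_loss(predictions, labels) -> float:
    """Mean over the eight heads of plain cross-entropy against one-hot
    binary semantic labels."""
    predictions = list(predictions)
    labels = list(labels)
    if len(predictions) != len(labels):
        raise ValueError(
            f"{len(predictions)} predictions vs {len(labels)} labels")
    return float(np.mean([
        cross_entropy(_onehot(int(y)), p)
        for p, y in zip(predictions, labels)]))


def total_loss(fdid: FDIDOutput, dr: DROutput | None, labels: dict,
               cfg: LossConfig, index: int = 0) -> float:
    """Stage-dependent objective for one sample.

    ``labels`` carries ``individual`` and ``panel`` class indices plus
    ``semantic``, a mapping of the eight feature names to binary labels.
    Panel-excluded cases must be filtered before training.
    """
    cfg.validate()
    y0, y1 = labels["individual"], labels["panel"]
    if y1 not in (0, 1):
        raise ValueError("panel label missing or excluded; filter upstream")
    sem_preds = [fdid.semantic[f][index] for f in SEMANTIC_FEATURES]
    sem_labels = [labels["semantic"][f] for f in SEMANTIC_FEATURES]
    loss = (collaborative_loss(fdid.individual[index], y0, y1, cfg.epsilon)
            + collaborative_loss(fdid.panel[index], y1, y0,
                                 cfg.epsilon_panel)
            + cfg.semantic_weight * semantic_loss(sem_preds, sem_labels))
    if cfg.stage == "joint":
        if dr is None:
            raise ValueError("joint stage requires refinement outputs")
        loss += collaborative_loss(dr.individual_refined[index], y0, y1,
                                   cfg.epsilon)
        loss += collaborative_loss(dr.panel_refined[index], y1, y0,
                                   cfg.epsilon_panel)
    return loss


def batch_loss_and_grads(fdid: FDIDOutput, dr: DROutput | None,
                         batch_labels: list[dict], cfg: LossConfig):
    """Mean loss over a batch plus gradients w.r.t. every emitted
    probability vector (canonical head order, then the two refined heads).

    Returns ``(loss, head_grads, dr_grads)`` with gradients already scaled
    by 1/N, ready for :meth:`NoduleNet.backward`.
    """
    cfg.validate()
    n = len(batch_labels)
    vectors = fdid.vectors()
    head_grads = [np.zeros_like(v) for v in vectors]
    dr_grads = None
    if cfg.stage == "joint":
        dr_grads = (np.zeros_like(dr.individual_refined),
                    np.zeros_like(dr.panel_refined))
    total = 0.0
    w = cfg.semantic_weight
    for i, lab in enumerate(batch_labels):
        total += total_loss(fdid, dr, lab, cfg, index=i)
        y0, y1 = lab["individual"], lab["panel"]
        for j, f in enumerate(SEMANTIC_FEATURES):
            q = _onehot(int(lab["semantic"][f]))
            head_grads[j][i] = (w / 8.0 / n) * (
                -q / np.maximum(vectors[j][i], PROB_FLOOR))
        head_grads[8][i] = collaborative_loss_grad(
            vectors[8][i], y0, y1, cfg.epsilon) / n
        head_grads[9][i] = collaborative_loss_grad(
            vectors[9][i], y1, y0, cfg.epsilon_panel) / n
        if cfg.stage == "joint":
            dr_grads[0][i] = collaborative_loss_grad(
                dr.individual_refined[i], y0, y1, cfg.epsilon) / n
            dr_grads[1][i] = collaborative_loss_grad(
                dr.panel_refined[i], y1, y0, cfg.epsilon_panel) / n
    return total / n, head_grads, dr_grads
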