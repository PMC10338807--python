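"""Shared 3D feature extractor: a residual network whose bottleneck stages
mix parallel grouped convolutions of kernel size 3/5/7.

The block design splits the bottleneck's reduced feature map into several
channel groups ("branches"), pushes each branch through its own grouped 3D
convolution at a branch-specific kernel size, and concatenates the results,
so a single block sees the nodule at several receptive-field scales at once.
The default configuration is the 50-layer variant used for malignancy
assessment: four stages with bottleneck widths 48/96/192/384, expansion
factor 4, block counts 3/4/6/3, mapping a 2-channel 80x80x80 input through
the spatial ladder 40/20/10/5 to a 1024-dimensional shared feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    BatchNorm3d,
    Conv3d,
    GlobalAvgPool3d,
    Linear,
    Module,
    ReLU,
    Sequential,
)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BranchSpec:
    """One branch of a multi-kernel bottleneck convolution."""
    kernel: int
    width: int
    groups: int

    def validate(self):
        if self.kernel % 2 == 0:
            raise ValueError(f"kernel must be odd, got {self.kernel}")
        if self.width % self.groups:
            raise ValueError(
                f"width {self.width} not divisible by groups {self.groups}")


@dataclass(frozen=True)
class BConvSpec:
    """Ordered branch list; branch widths partition the block's input."""
    branches: tuple[BranchSpec, ...]

    @property
    def widths(self) -> list[int]:
        return [b.width for b in self.branches]

    @property
    def total_width(self) -> int:
        return sum(self.widths)

    def validate(self):
        for b in self.branches:
            b.validate()


@dataclass(frozen=True)
class StageSpec:
    reduce_width: int
    bconv: BConvSpec
    expand_width: int
    blocks: int
    downsample: bool

    def validate(self):
        self.bconv.validate()
        if self.bconv.total_width != self.reduce_width:
            raise ValueError(
                f"branch widths {self.bconv.widths} sum to "
                f"{self.bconv.total_width}, expected {self.reduce_width}")
        if self.blocks < 1:
            raise ValueError("stage needs at least one block")


@dataclass(frozen=True)
class BackboneConfig:
    stem_width: int = 64
    stem_kernel: int = 7
    stem_stride: int = 2
    stages: tuple[StageSpec, ...] = ()
    shared_dim: int = 1024
    in_channels: int = 2

    def validate(self):
        if len(self.stages) != 4:
            raise ValueError("backbone requires exactly 4 stages")
        for s in self.stages:
            s.validate()

    def to_dict(self) -> dict:
        return {
            "stem_width": self.stem_width,
            "stem_kernel": self.stem_kernel,
            "stem_stride": self.stem_stride,
            "shared_dim": self.shared_dim,
            "in_channels": self.in_channels,
            "stages": [
                {
                    "reduce_width": s.reduce_width,
                    "branches": [[b.kernel, b.width, b.groups]
                                 for b in s.bconv.branches],
                    "expand_width": s.expand_width,
                    "blocks": s.blocks,
                    "downsample": s.downsample,
                }
                for s in self.stages
            ],
        }

    @staticmethod
    def from_dict(d: dict) -> "BackboneConfig":
        stages = tuple(
            StageSpec(
                reduce_width=s["reduce_width"],
                bconv=BConvSpec(tuple(BranchSpec(*b) for b in s["branches"])),
                expand_width=s["expand_width"],
                blocks=s["blocks"],
                downsample=s["downsample"],
            )
            for s in d["stages"]
        )
        cfg = BackboneConfig(
            stem_width=d.get("stem_width", 64),
            stem_kernel=d.get("stem_kernel", 7),
            stem_stride=d.get("stem_stride", 2),
            stages=stages,
            shared_dim=d.get("shared_dim", 1024),
            in_channels=d.get("in_channels", 2),
        )
        cfg.validate()
        return cfg


def _stage(reduce_width, branches, expand_width, blocks, downsample):
    return StageSpec(
        reduce_width=reduce_width,
        bconv=BConvSpec(tuple(BranchSpec(*b) for b in branches)),
        expand_width=expand_width,
        blocks=blocks,
        downsample=downsample,
    )


def default_config() -> BackboneConfig:
    """Full-size configuration (input 2x80^3, output 1024-d).

    Stage table: bottleneck widths 48/96/192/384 with expansion x4, branch
    kernels 7/5/3/5/7 narrowing to a single 3^3 branch in stage 4, grouped
    with G=8 on the 7^3 branches and G=4 on the 5^3 branches.
    """
    cfg = BackboneConfig(stages=(
        _stage(48, [(7, 8, 8), (5, 8, 4), (3, 16, 1), (5, 8, 4), (7, 8, 8)],
               192, 3, False),
        _stage(96, [(7, 16, 8), (5, 16, 4), (3, 32, 1), (5, 16, 4),
                    (7, 16, 8)], 384, 4, True),
        _stage(192, [(5, 48, 4), (3, 96, 1), (5, 48, 4)], 768, 6, True),
        _stage(384, [(3, 384, 1)], 1536, 3, True),
    ))
    cfg.validate()
    return cfg


def reduced_config() -> BackboneConfig:
    """Quarter-width, half-depth variant for 32^3 inputs (CPU micro-runs)."""
    cfg = BackboneConfig(
        stem_width=16,
        stages=(
            _stage(12, [(7, 2, 2), (5, 2, 2), (3, 4, 1), (5, 2, 2),
                        (7, 2, 2)], 48, 2, False),
            _stage(24, [(7, 4, 4), (5, 4, 4), (3, 8, 1), (5, 4, 4),
                        (7, 4, 4)], 96, 2, True),
            _stage(48, [(5, 12, 4), (3, 24, 1), (5, 12, 4)], 192, 3, True),
            _stage(96, [(3, 96, 1)], 384, 2, True),
        ),
        shared_dim=256,
    )
    cfg.validate()
    return cfg


def tiny_config() -> BackboneConfig:
    """Minimal 4-stage network for 16^3 inputs; unit tests only."""
    cfg = BackboneConfig(
        stem_width=8,
        stem_kernel=3,
        stages=(
            _stage(4, [(3, 4, 1)], 16, 1, False),
            _stage(8, [(3, 4, 1), (3, 4, 1)], 32, 1, True),
            _stage(16, [(3, 16, 1)], 64, 1, True),
            _stage(32, [(3, 32, 1)], 128, 1, True),
        ),
        shared_dim=64,
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# functional pieces
# ---------------------------------------------------------------------------

def split_channels(x: np.ndarray, widths) -> list[np.ndarray]:
    """Split a (N,C,D,H,W) map into contiguous channel slices.

    Concatenating the returned views along the channel axis reproduces the
    input exactly.
    """
    widths = list(widths)
    if sum(widths) != x.shape[1]:
        raise ValueError(
            f"widths {widths} sum to {sum(widths)}, input has {x.shape[1]} "
            "channels")
    out, start = [], 0
    for w in widths:
        out.append(x[:, start:start + w])
        start += w
    return out


class BConv(Module):
    """Split -> per-branch grouped conv (+BN+ReLU) -> concat.

    Channel count and spatial shape are preserved; each branch keeps its own
    batch-norm statistics.
    """

    def __init__(self, spec: BConvSpec, rng: np.random.Generator):
        spec.validate()
        self.spec = spec
        self.branches = [
            Sequential(
                Conv3d(b.width, b.width, b.kernel, groups=b.groups, rng=rng),
                BatchNorm3d(b.width),
                ReLU(),
            )
            for b in spec.branches
        ]

    def forward(self, x, train: bool = False):
        parts = split_channels(x, self.spec.widths)
        outs = [br.forward(p, train=train)
                for br, p in zip(self.branches, parts)]
        return np.concatenate(outs, axis=1)

    def backward(self, gy):
        gparts = split_channels(gy, self.spec.widths)
        gx = [br.backward(np.ascontiguousarray(g))
              for br, g in zip(self.branches, gparts)]
        return np.concatenate(gx, axis=1)


class BottleneckBlock(Module):
    """Residual bottleneck: 1^3 reduce -> multi-kernel BConv -> 1^3 expand.

    The spatial stride (2 in the first block of downsampling stages) lives in
    the reduce convolution and the shortcut projection.
    """

    def __init__(self, cin: int, stage: StageSpec, stride: int,
                 rng: np.random.Generator):
        ew = stage.expand_width
        self.reduce = Sequential(
            Conv3d(cin, stage.reduce_width, 1, stride=stride, rng=rng),
            BatchNorm3d(stage.reduce_width), ReLU())
        self.bconv = BConv(stage.bconv, rng)
        self.expand = Sequential(
            Conv3d(stage.reduce_width, ew, 1, rng=rng), BatchNorm3d(ew))
        if cin != ew or stride != 1:
            self.shortcut = Sequential(
                Conv3d(cin, ew, 1, stride=stride, rng=rng), BatchNorm3d(ew))
        else:
            self.shortcut = None
        self._relu_mask = None

    def forward(self, x, train: bool = False):
        f = self.expand.forward(
            self.bconv.forward(self.reduce.forward(x, train=train),
                               train=train), train=train)
        s = x if self.shortcut is None else self.shortcut.forward(
            x, train=train)
        y = f + s
        out = np.maximum(y, 0.0)
        if train:
            self._relu_mask = y > 0
        return out

    def backward(self, gy):
        gy = gy * self._relu_mask
        self._relu_mask = None
        gf = self.reduce.backward(
            self.bconv.backward(self.expand.backward(gy)))
        gs = gy if self.shortcut is None else self.shortcut.backward(gy)
        return gf + gs


class Backbone(Module):
    """Stem -> 4 bottleneck stages -> global average pool -> shared feature.

    ``forward(..., record=list)`` appends each stage's output spatial shape,
    which the architecture tests use to check the 40/20/10/5 ladder.
    """

    def __init__(self, config: BackboneConfig | None = None,
                 rng: np.random.Generator | None = None):
        config = config or default_config()
        config.validate()
        rng = rng or np.random.default_rng(0)
        self.config = config
        self.stem = Sequential(
            Conv3d(config.in_channels, config.stem_width, config.stem_kernel,
                   stride=config.stem_stride, rng=rng),
            BatchNorm3d(config.stem_width), ReLU())
        blocks = []
        cin = config.stem_width
        for stage in config.stages:
            for b in range(stage.blocks):
                stride = 2 if (b == 0 and stage.downsample) else 1
                blocks.append(BottleneckBlock(cin, stage, stride, rng))
                cin = stage.expand_width
        self.blocks = blocks
        self._stage_bounds = np.cumsum(
            [s.blocks for s in config.stages]).tolist()
        self.pool = GlobalAvgPool3d()
        self.fc = Linear(config.stages[-1].expand_width, config.shared_dim,
                         rng=rng)

    def forward(self, x, train: bool = False, record: list | None = None):
        if x.ndim == 4:
            x = x[None]
        if x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels}-channel input, "
                f"got shape {x.shape}")
        if not np.all(np.isfinite(x)):
            raise ValueError("input contains non-finite values")
        h = self.stem.forward(x, train=train)
        for i, block in enumerate(self.blocks):
            h = block.forward(h, train=train)
            if record is not None and (i + 1) in self._stage_bounds:
                record.append(h.shape[2:])
        pooled = self.pool.forward(h, train=train)
        return self.fc.forward(pooled, train=train)

    def backward(self, gy):
        g = self.pool.backward(self.fc.backward(gy))
        for block in reversed(self.blocks):
            g = block.backward(g)
        return self.stem.backward(g)


# ---------------------------------------------------------------------------
# parameter accounting
# ---------------------------------------------------------------------------

def _conv_params(cin, cout, k, groups=1, bias=False):
    n = cout * (cin // groups) * k**3
    return n + (cout if bias else 0)


def parameter_count(config: BackboneConfig) -> int:
    """Exact learnable-parameter count, from the config alone.

    Counts convolution and linear weights plus batch-norm scale/shift pairs,
    mirroring the constructed network layer for layer (independent of any
    instantiation; the test suite cross-checks against a parameter walk of
    the built model).
    """
    config.validate()
    total = _conv_params(config.in_channels, config.stem_width,
                         config.stem_kernel) + 2 * config.stem_width
    cin = config.stem_width
    for stage in config.stages:
        for b in range(stage.blocks):
            stride = 2 if (b == 0 and stage.downsample) else 1
            rw, ew = stage.reduce_width, stage.expand_width
            total += _conv_params(cin, rw, 1) + 2 * rw
            for br in stage.bconv.branches:
                total += _conv_params(br.width, br.width, br.kernel,
                                      br.groups) + 2 * br.width
            total += _conv_params(rw, ew, 1) + 2 * ew
            if cin != ew or stride != 1:
                total += _conv_params(cin, ew, 1) + 2 * ew
            cin = ew
    # final projection has a bias
    total += config.stages[-1].expand_width * config.shared_dim \
        + config.shared_dim
    return total
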