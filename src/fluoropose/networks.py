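"""Model builders for the two-stage pose-estimation architecture.

Stage one ("shadownet") is a segmentation network that extracts the
implant silhouette from the x-ray; it takes two channels -- the x-ray and
a rendered-shadow feedback image -- and emits one logit map at input
resolution.  Stage two ("synthnet") is a per-implant-combination
regression network mapping a binary silhouette to the 18 pose targets
(two translations of 3 plus two 6D rotation encodings).

All normalisation is instance normalisation: batch statistics are
unusable at the batch sizes (1-4) these models are trained with, and
per-sample normalisation keeps gradient accumulation exactly equivalent
to large batches.

Three capacity scales share each topology.  ``paper`` reproduces the
published architectures (a ResNeXt-50 32x4d regressor and an atrous
encoder-decoder segmenter with ASPP); ``tiny`` and ``small`` shrink depth
and width so the full pipeline trains on a desktop CPU in minutes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .nn.layers import Module, Parameter, Sequential

__all__ = [
    "ModelSpec",
    "StagedNetwork",
    "build_synthnet",
    "build_shadownet",
    "build_model",
    "freeze_prefix",
    "save_checkpoint",
    "load_checkpoint",
]

_SCALES = ("tiny", "small", "paper")
#: native input resolution per scale (pixels); tiny/small heads flatten the
#: final feature map, so they are built for a fixed resolution
_DEFAULT_IMAGE_SIZE = {"tiny": 64, "small": 64, "paper": 512}


@dataclass(frozen=True)
class ModelSpec:
    """Architecture descriptor stored alongside every checkpoint."""

    stage: str
    scale: str = "tiny"
    image_size: int | None = None
    normalisation: str = "instance"

    def __post_init__(self) -> None:
        if self.stage not in ("shadownet", "synthnet"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.scale not in _SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {_SCALES}")
        if self.normalisation != "instance":
            raise ValueError("only instance normalisation is supported")
        if self.image_size is None:
            object.__setattr__(self, "image_size", _DEFAULT_IMAGE_SIZE[self.scale])

    @property
    def input_channels(self) -> int:
        return 2 if self.stage == "shadownet" else 1

    @property
    def output_length(self) -> int | None:
        return 18 if self.stage == "synthnet" else None


class StagedNetwork(Sequential):
    """Sequential model whose top-level blocks are named; the block list is
    the unit of granularity for prefix freezing."""

    def __init__(self, blocks: list[tuple[str, Module]], spec: ModelSpec):
        super().__init__(*[m for _, m in blocks])
        self.block_names = [name for name, _ in blocks]
        self.spec = spec

    def parameter_checksum(self) -> float:
        return float(sum(np.abs(p.data).sum() for p in self.parameters()))


def _conv_block(cin, cout, rng, stride=1, groups=1, k=3, dilation=1) -> Sequential:
    pad = dilation * (k - 1) // 2
    return Sequential(
        nn.Conv2d(cin, cout, k, stride=stride, padding=pad, dilation=dilation,
                  groups=groups, rng=rng),
        nn.InstanceNorm2d(cout),
        nn.ReLU(),
    )


def _resnext_bottleneck(cin, cout, width, rng, stride=1, groups=32) -> nn.Residual:
    body = Sequential(
        nn.Conv2d(cin, width, 1, rng=rng),
        nn.InstanceNorm2d(width),
        nn.ReLU(),
        nn.Conv2d(width, width, 3, stride=stride, padding=1, groups=groups, rng=rng),
        nn.InstanceNorm2d(width),
        nn.ReLU(),
        nn.Conv2d(width, cout, 1, rng=rng),
        nn.InstanceNorm2d(cout),
    )
    shortcut = None
    if stride != 1 or cin != cout:
        shortcut = Sequential(
            nn.Conv2d(cin, cout, 1, stride=stride, rng=rng),
            nn.InstanceNorm2d(cout),
        )
    return nn.Residual(body, shortcut)


def build_synthnet(spec: ModelSpec, seed: int) -> StagedNetwork:
    """Silhouette -> 18-vector pose regressor.

    The tiny/small heads flatten the final feature map instead of global
    average pooling so that the in-plane position of the silhouette stays
    directly observable to the dense layer; the paper scale keeps the
    canonical global-pooled ResNeXt head.
    """
    if spec.stage != "synthnet":
        raise ValueError("spec.stage must be 'synthnet'")
    rng = np.random.default_rng(seed)
    size = spec.image_size
    if spec.scale == "tiny":
        feat = size // 8
        blocks = [
            ("stem", _conv_block(1, 8, rng, stride=2)),
            ("stage1", _conv_block(8, 16, rng, stride=2, groups=4)),
            ("stage2", _conv_block(16, 32, rng, stride=2, groups=4)),
            ("head", Sequential(nn.Flatten(), nn.Linear(32 * feat * feat, 18, rng=rng))),
        ]
    elif spec.scale == "small":
        feat = size // 16
        blocks = [
            ("stem", _conv_block(1, 16, rng, stride=2)),
            ("stage1", _resnext_bottleneck(16, 32, 16, rng, stride=2, groups=4)),
            ("stage2", _resnext_bottleneck(32, 64, 32, rng, stride=2, groups=4)),
            ("stage3", _resnext_bottleneck(64, 64, 32, rng, stride=2, groups=4)),
            ("head", Sequential(nn.Flatten(), nn.Linear(64 * feat * feat, 18, rng=rng))),
        ]
    else:  # ResNeXt-50 (32 groups of width 4), instance-normalised
        layers, cin = [], 64
        stem = Sequential(
            nn.Conv2d(1, 64, 7, stride=2, padding=3, rng=rng),
            nn.InstanceNorm2d(64),
            nn.ReLU(),
            nn.MaxPool2d(3, stride=2, padding=1),
        )
        blocks = [("stem", stem)]
        for si, (n_blocks, width, cout, stride) in enumerate(
            [(3, 128, 256, 1), (4, 256, 512, 2), (6, 512, 1024, 2), (3, 1024, 2048, 2)]
        ):
            stage = []
            for b in range(n_blocks):
                stage.append(
                    _resnext_bottleneck(cin, cout, width, rng, stride=stride if b == 0 else 1)
                )
                cin = cout
            blocks.append((f"stage{si + 1}", Sequential(*stage)))
        blocks.append(("head", Sequential(nn.GlobalAvgPool2d(), nn.Linear(2048, 18, rng=rng))))
    return StagedNetwork(blocks, spec)


class _ImagePoolBranch(Module):
    """ASPP image-level branch: global pool, 1x1 conv, broadcast back."""

    def __init__(self, cin, cout, rng):
        self.conv = nn.Conv2d(cin, cout, 1, rng=rng)

    def children(self):
        yield self.conv

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._hw = x.shape[-2:]
        pooled = x.mean(axis=(2, 3), keepdims=True)
        y = self.conv.forward(pooled)
        return np.broadcast_to(y, y.shape[:2] + self._hw).copy()

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        g = grad_out.sum(axis=(2, 3), keepdims=True)
        gx = self.conv.backward(g)
        h, w = self._hw
        return np.broadcast_to(gx / (h * w), gx.shape[:2] + self._hw).copy()


class _Parallel(Module):
    """Run branches on the same input and concatenate along channels."""

    def __init__(self, *branches: Module):
        self.branches = list(branches)

    def children(self):
        return iter(self.branches)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._outs = [b.forward(x) for b in self.branches]
        self._splits = np.cumsum([o.shape[1] for o in self._outs])[:-1]
        return np.concatenate(self._outs, axis=1)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        grads = np.split(grad_out, self._splits, axis=1)
        gx = None
        for b, g in zip(self.branches, grads):
            gb = b.backward(g)
            gx = gb if gx is None else gx + gb
        return gx


def build_shadownet(spec: ModelSpec, seed: int) -> StagedNetwork:
    """Two-channel x-ray + feedback-shadow -> one-logit silhouette map.

    Output resolution always equals input resolution; the feedback channel
    may be all zeros (the black-image bootstrap of the first iteration).
    """
    if spec.stage != "shadownet":
        raise ValueError("spec.stage must be 'shadownet'")
    rng = np.random.default_rng(seed)
    if spec.scale == "tiny":
        blocks = [
            ("enc1", _conv_block(2, 8, rng, stride=2)),
            ("enc2", _conv_block(8, 16, rng, stride=2)),
            ("mid", _conv_block(16, 16, rng)),
            ("dec1", Sequential(nn.UpsampleNearest(2), *_conv_block(16, 8, rng)._modules)),
            ("dec2", Sequential(nn.UpsampleNearest(2),
                                nn.Conv2d(8, 1, 3, padding=1, rng=rng))),
        ]
    elif spec.scale == "small":
        blocks = [
            ("enc1", _conv_block(2, 16, rng, stride=2)),
            ("enc2", _conv_block(16, 32, rng, stride=2)),
            ("mid", Sequential(
                _Parallel(
                    _conv_block(32, 8, rng, k=1),
                    _conv_block(32, 8, rng, dilation=2),
                    _conv_block(32, 8, rng, dilation=4),
                    _ImagePoolBranch(32, 8, rng),
                ),
                *_conv_block(32, 32, rng, k=1)._modules,
            )),
            ("dec1", Sequential(nn.UpsampleNearest(2), *_conv_block(32, 16, rng)._modules)),
            ("dec2", Sequential(nn.UpsampleNearest(2),
                                nn.Conv2d(16, 1, 3, padding=1, rng=rng))),
        ]
    else:  # ResNet-50 backbone at output stride 16 + ASPP head
        cin = 64
        stem = Sequential(
            nn.Conv2d(2, 64, 7, stride=2, padding=3, rng=rng),
            nn.InstanceNorm2d(64),
            nn.ReLU(),
            nn.MaxPool2d(3, stride=2, padding=1),
        )
        blocks = [("stem", stem)]
        for si, (n_blocks, width, cout, stride, dil) in enumerate(
            [(3, 64, 256, 1, 1), (4, 128, 512, 2, 1), (6, 256, 1024, 2, 1), (3, 512, 2048, 1, 2)]
        ):
            stage = []
            for b in range(n_blocks):
                stage.append(
                    _resnext_bottleneck(cin, cout, width, rng,
                                        stride=stride if b == 0 else 1, groups=1)
                )
                cin = cout
            blocks.append((f"stage{si + 1}", Sequential(*stage)))
        aspp = Sequential(
            _Parallel(
                _conv_block(2048, 256, rng, k=1),
                _conv_block(2048, 256, rng, dilation=6),
                _conv_block(2048, 256, rng, dilation=12),
                _conv_block(2048, 256, rng, dilation=18),
                _ImagePoolBranch(2048, 256, rng),
            ),
            *_conv_block(5 * 256, 256, rng, k=1)._modules,
        )
        blocks.append(("aspp", aspp))
        blocks.append(("head", Sequential(
            nn.Conv2d(256, 1, 1, rng=rng),
            nn.UpsampleNearest(16),
        )))
    return StagedNetwork(blocks, spec)


def build_model(spec: ModelSpec, seed: int) -> StagedNetwork:
    builder = build_shadownet if spec.stage == "shadownet" else build_synthnet
    return builder(spec, seed)


def freeze_prefix(model: StagedNetwork, fraction: float) -> tuple[int, int]:
    """Mark the parameters of the first ``ceil(fraction * B)`` of the model's
    ``B`` ordered top-level blocks as non-trainable; the rest are made
    trainable.  Returns (frozen, total) parameter counts.

    Freezing is by block count rather than parameter count so the frozen
    prefix is stable under width changes between capacity scales.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    n_blocks = len(model)
    n_frozen = int(np.ceil(fraction * n_blocks)) if fraction > 0 else 0
    frozen = 0
    for i, block in enumerate(model.children()):
        flag = i >= n_frozen
        for p in block.parameters():
            p.trainable = flag
            if not flag:
                frozen += p.size
    return frozen, model.num_parameters()


def save_checkpoint(model: StagedNetwork, path, seed: int | None = None,
                    norm_constants: dict | None = None, extra: dict | None = None) -> None:
    """Persist weights plus the spec, seed, and translation-normalisation
    constants needed to rebuild and use the model."""
    meta = {
        "spec": asdict(model.spec),
        "seed": seed,
        "norm_constants": norm_constants,
        "extra": extra or {},
    }
    state = model.state_dict()
    np.savez(path, __meta__=json.dumps(meta), **state)


def load_checkpoint(path) -> tuple[StagedNetwork, dict]:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    spec = ModelSpec(**meta["spec"])
    model = build_model(spec, seed=meta.get("seed") or 0)
    state = {k: data[k] for k in data.files if k != "__meta__"}
    model.load_state_dict(state)
    return model, meta
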