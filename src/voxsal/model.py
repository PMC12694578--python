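"""Truncated 3D residual classifier: architecture spec, inflation, builder.

The classifier is a residual network whose 3D kernels can be constructed by
replicating 2D kernels along the depth axis ("weight inflation"), so a
2D-pretrained network can be transferred to volumetric input.  The default
architecture truncates the 18-layer basic-block plan down to 12 learnable
layers — a 7x7x7 single-channel stem (64 channels, stride 2) with max-pool,
stages of [2, 2, 1] basic blocks at 64/128/256 channels, spatial dropout 0.4,
global average pooling and a 256-to-2 fully connected head — which lands at
4.7M trainable parameters versus 33.2M for the full-depth variant.

"Learnable layers" follow the standard residual-network counting convention:
stem conv + two convs per basic block + the fully connected layer;
projection shortcuts are excluded from the layer count but their parameters
are, of course, real and counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .nn import (
    BasicBlock,
    BatchNorm3d,
    Conv3d,
    GlobalAvgPool,
    Linear,
    MaxPool3d,
    Param,
    ReLU,
    SpatialDropout3d,
)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Layout of the residual classifier.

    ``stages`` is a tuple of (n_basic_blocks, channels); every stage after
    the first downsamples by stride 2 in its first block.  The head is
    spatial dropout -> global average pool -> fully connected to 2 classes.
    """

    in_channels: int = 1
    stem_channels: int = 64
    stem_kernel: int = 7
    stem_stride: int = 2
    stem_pool: bool = True
    stages: tuple[tuple[int, int], ...] = ((2, 64), (2, 128), (1, 256))
    stage_strides: Optional[tuple[int, ...]] = None  # default: 1, then 2 per stage
    dropout: float = 0.4
    n_classes: int = 2

    def stride_for_stage(self, si: int) -> int:
        if self.stage_strides is not None:
            return self.stage_strides[si]
        return 1 if si == 0 else 2

    @property
    def learnable_layer_count(self) -> int:
        return 1 + 2 * sum(n for n, _ in self.stages) + 1

    @property
    def head_width(self) -> int:
        return self.stages[-1][1]

    def to_dict(self) -> dict:
        return {
            "in_channels": self.in_channels,
            "stem_channels": self.stem_channels,
            "stem_kernel": self.stem_kernel,
            "stem_stride": self.stem_stride,
            "stem_pool": self.stem_pool,
            "stages": [list(s) for s in self.stages],
            "stage_strides": None if self.stage_strides is None else list(self.stage_strides),
            "dropout": self.dropout,
            "n_classes": self.n_classes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        d = dict(d)
        d["stages"] = tuple(tuple(s) for s in d["stages"])
        if d.get("stage_strides") is not None:
            d["stage_strides"] = tuple(d["stage_strides"])
        return cls(**d)


def resnet18_3d_spec() -> ArchitectureSpec:
    """The full-depth 18-layer variant: [2,2,2,2] blocks at 64..512 channels."""
    return ArchitectureSpec(stages=((2, 64), (2, 128), (2, 256), (2, 512)))


def reduced_spec(width: int = 8, stages: tuple[tuple[int, int], ...] = ((1, 8), (1, 16))) -> ArchitectureSpec:
    """A narrow desk-scale layout for small synthetic volumes.

    A 3-cubed stem (the 7-cubed stem is proportioned for 224-cubed scans),
    no stem max-pool, and two single-block stages with one stride-2
    downsampling keep the terminal feature grid at 1/4 of the input
    resolution on a 32-cubed volume — a compact receptive field that lets
    saliency resolve individual phantom areas at tractable cost.
    """
    return ArchitectureSpec(
        stem_channels=width,
        stem_kernel=3,
        stem_pool=False,
        stages=stages,
        stage_strides=(1, 2),
    )


def inflate_2d_to_3d(kernel2d: np.ndarray, depth_scale: bool = False) -> np.ndarray:
    """Replicate a 2D kernel block along a new depth axis.

    ``kernel2d`` is (k, k, C_in, C_out) with a square spatial kernel; the
    result is (k, k, k, C_in, C_out) with every depth slice equal to the 2D
    kernel, multiplying the parameter count by k.  With ``depth_scale`` the
    slices are divided by k so a depth-constant input reproduces the 2D
    activation scale.
    """
    kernel2d = np.asarray(kernel2d)
    if kernel2d.ndim != 4 or kernel2d.shape[0] != kernel2d.shape[1]:
        raise ValueError(f"expected square (k, k, C_in, C_out) kernel, got {kernel2d.shape}")
    k = kernel2d.shape[0]
    out = np.broadcast_to(kernel2d[None], (k,) + kernel2d.shape).copy()
    if depth_scale:
        out = out / k
    return out


class ResidualClassifier3D:
    """Sequential residual network over (B, C, D, H, W) volumes.

    ``feature_index`` marks the output of the final residual stage — the
    designated layer for gradient-weighted class activation mapping (the
    deepest layer that still has spatial extent, before dropout and pooling).
    """

    def __init__(self, spec: ArchitectureSpec, rng: Optional[np.random.Generator] = None):
        self.spec = spec
        rng = rng or np.random.default_rng(0)
        layers: list = [
            Conv3d(
                spec.in_channels,
                spec.stem_channels,
                spec.stem_kernel,
                stride=spec.stem_stride,
                rng=rng,
                name="stem",
            ),
            BatchNorm3d(spec.stem_channels, name="stem_bn"),
            ReLU(),
        ]
        if spec.stem_pool:
            layers.append(MaxPool3d(3, 2, 1))
        c_prev = spec.stem_channels
        for si, (n_blocks, c) in enumerate(spec.stages):
            for bi in range(n_blocks):
                stride = spec.stride_for_stage(si) if bi == 0 else 1
                layers.append(
                    BasicBlock(c_prev, c, stride=stride, rng=rng, name=f"s{si}b{bi}")
                )
                c_prev = c
        self.feature_index = len(layers)  # boundary: features feed the head
        self.dropout = SpatialDropout3d(spec.dropout)
        self.gap = GlobalAvgPool()
        self.fc = Linear(c_prev, spec.n_classes, rng=rng, name="fc")
        layers += [self.dropout, self.gap, self.fc]
        self.layers = layers

    # -- parameters -------------------------------------------------------
    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    # -- passes -----------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def forward_features(self, x: np.ndarray, train: bool = False):
        """Return (logits, feature maps at the designated layer)."""
        for layer in self.layers[: self.feature_index]:
            x = layer.forward(x, train)
        feats = x
        for layer in self.layers[self.feature_index :]:
            x = layer.forward(x, train)
        return x, feats

    def backward(self, gy: np.ndarray, upto: int = 0) -> np.ndarray:
        """Backpropagate from the logits down to layer boundary ``upto``."""
        for layer in reversed(self.layers[upto:]):
            gy = layer.backward(gy)
        return gy

    def backward_to_features(self, glogits: np.ndarray) -> np.ndarray:
        """Gradient of a scalar in logit space w.r.t. the designated features."""
        return self.backward(glogits, upto=self.feature_index)

    def predict_scores(self, volumes: np.ndarray) -> np.ndarray:
        """Pre-softmax class scores in deterministic eval mode."""
        return self.forward(volumes, train=False)

    # -- (de)serialization -------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, p in enumerate(self.params()):
            out[f"param_{i:03d}"] = p.value
        bi = 0
        for layer in self.layers:
            if isinstance(layer, BatchNorm3d):
                out[f"bn_{bi:03d}_mean"] = layer.running_mean
                out[f"bn_{bi:03d}_var"] = layer.running_var
                bi += 1
            elif isinstance(layer, BasicBlock):
                bns = [layer.bn1, layer.bn2] + ([layer.proj_bn] if layer.projects else [])
                for bn in bns:
                    out[f"bn_{bi:03d}_mean"] = bn.running_mean
                    out[f"bn_{bi:03d}_var"] = bn.running_var
                    bi += 1
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value[...] = arrays[f"param_{i:03d}"]
        bi = 0
        for layer in self.layers:
            if isinstance(layer, BatchNorm3d):
                layer.running_mean[...] = arrays[f"bn_{bi:03d}_mean"]
                layer.running_var[...] = arrays[f"bn_{bi:03d}_var"]
                bi += 1
            elif isinstance(layer, BasicBlock):
                bns = [layer.bn1, layer.bn2] + ([layer.proj_bn] if layer.projects else [])
                for bn in bns:
                    bn.running_mean[...] = arrays[f"bn_{bi:03d}_mean"]
                    bn.running_var[...] = arrays[f"bn_{bi:03d}_var"]
                    bi += 1


def build_model(
    spec: ArchitectureSpec,
    init: str = "glorot-random",
    seed: int = 0,
    weights2d: Optional[dict[str, np.ndarray]] = None,
    depth_scale: bool = False,
) -> ResidualClassifier3D:
    """Construct the classifier, optionally inflating user-supplied 2D kernels.

    ``init="glorot-random"`` draws every weight from a seeded Glorot-uniform
    distribution (biases zero).  ``init="inflated-from-2d"`` replaces each
    convolution whose name appears in ``weights2d`` (mapping layer name to a
    (k, k, C_in, C_out) kernel) with its depth-replicated 3D inflation; the
    head stays Glorot-initialized, as it is task-specific.
    """
    model = ResidualClassifier3D(spec, rng=np.random.default_rng(seed))
    if init == "glorot-random":
        return model
    if init != "inflated-from-2d":
        raise ValueError(f"unknown init mode {init!r}")
    if not weights2d:
        raise ValueError("inflated-from-2d init requires a weights2d mapping")
    convs = _named_convs(model)
    for name, k2d in weights2d.items():
        if name not in convs:
            raise KeyError(f"no convolution named {name!r} in this architecture")
        conv = convs[name]
        k3d = inflate_2d_to_3d(k2d, depth_scale=depth_scale)
        # (k, k, k, C_in, C_out) -> (C_out, C_in, k, k, k)
        k3d = k3d.transpose(4, 3, 0, 1, 2)
        if k3d.shape != conv.weight.value.shape:
            raise ValueError(
                f"inflated kernel {k3d.shape} does not fit layer {name} "
                f"{conv.weight.value.shape}"
            )
        conv.weight.value[...] = k3d
    return model


def _named_convs(model: ResidualClassifier3D) -> dict[str, Conv3d]:
    out: dict[str, Conv3d] = {}
    for layer in model.layers:
        if isinstance(layer, Conv3d):
            out[layer.weight.name] = layer
        elif isinstance(layer, BasicBlock):
            for conv in [layer.conv1, layer.conv2] + ([layer.proj] if layer.projects else []):
                out[conv.weight.name] = conv
    return out


def count_parameters(model: ResidualClassifier3D) -> int:
    """Total size of all trainable arrays (running statistics excluded)."""
    return int(sum(p.value.size for p in model.params()))


def _all_batchnorms(model: ResidualClassifier3D) -> list[BatchNorm3d]:
    bns: list[BatchNorm3d] = []
    for layer in model.layers:
        if isinstance(layer, BatchNorm3d):
            bns.append(layer)
        elif isinstance(layer, BasicBlock):
            bns += [layer.bn1, layer.bn2]
            if layer.projects:
                bns.append(layer.proj_bn)
    return bns


def recalibrate_batchnorm(
    model: ResidualClassifier3D, x: np.ndarray, batch_size: int = 15
) -> None:
    """Recompute batch-norm running statistics over a reference input set.

    With few optimization steps the exponentially averaged statistics lag
    the final weights, which can wreck deterministic-eval predictions; this
    pass freezes the weights and replaces the running mean/variance of every
    normalization layer with exact aggregates over ``x`` (shaped
    (N, C, D, H, W)), processed in chunks.
    """
    bns = _all_batchnorms(model)
    for bn in bns:
        bn.begin_accumulate()
    for start in range(0, len(x), batch_size):
        model.forward(x[start : start + batch_size], train=True)
    for bn in bns:
        bn.end_accumulate()
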