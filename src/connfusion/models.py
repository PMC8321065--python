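"""Network architectures: 3D ResNet-18, MLP, and the fused classifier.

The fingerprint encoder is an 18-layer residual network whose 2D
convolutions are replaced by 3D ones.  The N-region axis of the
fingerprint is used as the input-channel axis, so the network convolves
over the three spatial axes only.  At full scale (116 regions on a
61x73x61 grid) the stage-by-stage output sizes are:

    conv1   5x5x5/64, stride 2, pad 3      -> 32 x 38 x 32 x 64
    maxpool 1x3x3, stride (1,2,2), pad (0,1,1) -> 32 x 19 x 16 x 64
    stage 1 [1x3x3, 64]  x2, stride 1      -> 32 x 19 x 16 x 64
    stage 2 [1x3x3, 128] x2, stride (1,2,2) -> 32 x 10 x 8 x 128
    stage 3 [3x3x3, 256] x2, stride (1,2,2) -> 32 x 5 x 4 x 256
    stage 4 [3x3x3, 512] x2, stride (1,2,2) -> 32 x 3 x 2 x 512
    global average pool                     -> 512
    fully connected                         -> 2

Paddings follow the unique smallest solutions of the stride arithmetic
above; residual stages use batch-normalised basic blocks with projection
shortcuts (1x1x1 conv at the block's stride) wherever shape changes.

The connectivity-vector encoder is an MLP with three 100-unit hidden
layers.  The multimodal classifier concatenates the ResNet's 512-D
post-pool feature with the MLP's 100-D last hidden activation (both
output layers bypassed) and feeds the 612-D vector through four
fully-connected layers ending in 2 logits.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .connectome import ConnectivityVector, FingerprintMap
from .dataio import CLASS_NAMES
from .errors import CheckpointError, ShapeError, ValidationError


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass
class ResNetConfig:
    in_channels: int = 116
    block_channels: tuple[int, ...] = (64, 128, 256, 512)
    conv1_kernel: tuple[int, int, int] = (5, 5, 5)
    conv1_stride: tuple[int, int, int] = (2, 2, 2)
    conv1_padding: tuple[int, int, int] = (3, 3, 3)
    pool_kernel: tuple[int, int, int] = (1, 3, 3)
    pool_stride: tuple[int, int, int] = (1, 2, 2)
    pool_padding: tuple[int, int, int] = (0, 1, 1)
    block_kernels: tuple[tuple[int, int, int], ...] = (
        (1, 3, 3), (1, 3, 3), (3, 3, 3), (3, 3, 3))
    block_strides: tuple[tuple[int, int, int], ...] = (
        (1, 1, 1), (1, 2, 2), (1, 2, 2), (1, 2, 2))
    out_classes: int = 2

    def __post_init__(self):
        for a, b in zip(self.block_channels, self.block_channels[1:]):
            if b != 2 * a:
                raise ValidationError("block_channels must strictly double")
        for stride in (self.conv1_stride, *self.block_strides):
            if any(s not in (1, 2) for s in stride):
                raise ValidationError("strides must be 1 or 2 per axis")

    @property
    def feature_dim(self) -> int:
        return self.block_channels[-1]


@dataclass
class MLPConfig:
    in_features: int = 6670
    hidden_sizes: tuple[int, ...] = (100, 100, 100)
    out_classes: int = 2

    def __post_init__(self):
        if len(self.hidden_sizes) != 3:
            raise ValidationError("MLP must have exactly 3 hidden layers")
        if min((self.in_features, *self.hidden_sizes, self.out_classes)) < 1:
            raise ValidationError("all layer sizes must be >= 1")

    @property
    def feature_dim(self) -> int:
        return self.hidden_sizes[-1]


@dataclass
class FusionConfig:
    resnet_feature_dim: int = 512
    mlp_feature_dim: int = 100
    head_sizes: tuple[int, ...] = (256, 64, 16, 2)

    def __post_init__(self):
        if len(self.head_sizes) != 4:
            raise ValidationError("fusion head must have exactly 4 layers")
        if self.head_sizes[-1] != 2:
            raise ValidationError("fusion head must end in 2 classes")

    @property
    def in_features(self) -> int:
        return self.resnet_feature_dim + self.mlp_feature_dim


@dataclass
class PredictionResult:
    logits: tuple[float, float]
    probabilities: tuple[float, float]
    predicted_class: str  # element of CLASS_NAMES


# ---------------------------------------------------------------------------
# architectures
# ---------------------------------------------------------------------------


class BasicBlock3d(nn.Module):
    """Two conv-BN stages with a residual shortcut (projected when the
    shape changes), ReLU after the sum."""

    def __init__(self, in_ch, out_ch, kernel, stride, *, rng, name):
        pad = tuple(k // 2 for k in kernel)
        self.conv1 = nn.Conv3d(in_ch, out_ch, kernel, stride, pad,
                               rng=rng, name=f"{name}.conv1")
        self.bn1 = nn.BatchNorm3d(out_ch)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv3d(out_ch, out_ch, kernel, 1, pad,
                               rng=rng, name=f"{name}.conv2")
        self.bn2 = nn.BatchNorm3d(out_ch)
        if in_ch != out_ch or tuple(nn._triple(stride)) != (1, 1, 1):
            self.shortcut = nn.Sequential(
                nn.Conv3d(in_ch, out_ch, 1, stride, 0,
                          rng=rng, name=f"{name}.shortcut"),
                nn.BatchNorm3d(out_ch),
            )
        else:
            self.shortcut = None
        self.relu2 = nn.ReLU()

    def forward(self, x):
        out = self.relu1(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        identity = self.shortcut(x) if self.shortcut is not None else x
        return self.relu2(out + identity)

    def backward(self, dout):
        d = self.relu2.bprop(dout)
        d_main = self.conv1.bprop(self.bn1.bprop(self.relu1.bprop(
            self.conv2.bprop(self.bn2.bprop(d)))))
        d_skip = self.shortcut.bprop(d) if self.shortcut is not None else d
        return d_main + d_skip


class ResNet3d(nn.Module):
    """3D ResNet-18 over (B, N_regions, H, W, D) fingerprints."""

    def __init__(self, config: ResNetConfig, *, rng: np.random.Generator):
        self.config = config
        c = config.block_channels
        self.conv1 = nn.Conv3d(config.in_channels, c[0], config.conv1_kernel,
                               config.conv1_stride, config.conv1_padding,
                               rng=rng, name="conv1")
        self.bn1 = nn.BatchNorm3d(c[0])
        self.relu1 = nn.ReLU()
        self.maxpool = nn.MaxPool3d(config.pool_kernel, config.pool_stride,
                                    config.pool_padding)
        stages = []
        in_ch = c[0]
        for i, (out_ch, kernel, stride) in enumerate(
                zip(c, config.block_kernels, config.block_strides), start=1):
            stages.append(nn.Sequential(
                BasicBlock3d(in_ch, out_ch, kernel, stride,
                             rng=rng, name=f"layer{i}.0"),
                BasicBlock3d(out_ch, out_ch, kernel, 1,
                             rng=rng, name=f"layer{i}.1"),
            ))
            in_ch = out_ch
        self.layer1, self.layer2, self.layer3, self.layer4 = stages
        self.avgpool = nn.GlobalAvgPool3d()
        self.fc = nn.Linear(config.feature_dim, config.out_classes,
                            rng=rng, name="fc")

    # named convolutional stages usable as Grad-CAM targets
    def conv_stages(self) -> dict[str, nn.Module]:
        return {"conv1": self.relu1, "maxpool": self.maxpool,
                "layer1": self.layer1, "layer2": self.layer2,
                "layer3": self.layer3, "layer4": self.layer4}

    def features(self, x):
        """Truncated mode: the 512-D post-average-pool feature vector."""
        x = self.maxpool(self.relu1(self.bn1(self.conv1(x))))
        for stage in (self.layer1, self.layer2, self.layer3, self.layer4):
            x = stage(x)
        return self.avgpool(x)

    def forward(self, x):
        return self.fc(self.features(x))

    def backward_features(self, dfeat):
        d = self.avgpool.bprop(dfeat)
        for stage in (self.layer4, self.layer3, self.layer2, self.layer1):
            d = stage.bprop(d)
        d = self.conv1.bprop(self.bn1.bprop(self.relu1.bprop(self.maxpool.bprop(d))))
        return d

    def backward(self, dout):
        return self.backward_features(self.fc.bprop(dout))


class MLP(nn.Module):
    """Fully-connected encoder over connectivity vectors."""

    def __init__(self, config: MLPConfig, *, rng: np.random.Generator):
        self.config = config
        sizes = (config.in_features, *config.hidden_sizes)
        self.hidden = [
            nn.Linear(a, b, rng=rng, name=f"hidden{i}")
            for i, (a, b) in enumerate(zip(sizes, sizes[1:]))
        ]
        self.relus = [nn.ReLU() for _ in self.hidden]
        self.out = nn.Linear(config.feature_dim, config.out_classes,
                             rng=rng, name="out")

    def features(self, x):
        """Truncated mode: the last hidden activation (100-D at full scale)."""
        for lin, act in zip(self.hidden, self.relus):
            x = act(lin(x))
        return x

    def forward(self, x):
        return self.out(self.features(x))

    def backward_features(self, dfeat):
        d = dfeat
        for lin, act in zip(reversed(self.hidden), reversed(self.relus)):
            d = lin.bprop(act.bprop(d))
        return d

    def backward(self, dout):
        return self.backward_features(self.out.bprop(dout))


class MultimodalNet(nn.Module):
    """Concatenation fusion of both encoders plus a 4-layer FC head.

    ``forward`` takes (fingerprint batch, connectivity batch); gradients
    are routed back through both branches.
    """

    def __init__(self, resnet: ResNet3d, mlp: MLP, fusion: FusionConfig,
                 *, rng: np.random.Generator):
        if resnet.config.feature_dim != fusion.resnet_feature_dim:
            raise ShapeError(
                f"resnet feature dim {resnet.config.feature_dim} != "
                f"fusion config {fusion.resnet_feature_dim}")
        if mlp.config.feature_dim != fusion.mlp_feature_dim:
            raise ShapeError(
                f"mlp feature dim {mlp.config.feature_dim} != "
                f"fusion config {fusion.mlp_feature_dim}")
        self.fusion = fusion
        self.resnet = resnet
        self.mlp = mlp
        sizes = (fusion.in_features, *fusion.head_sizes)
        self.head = [
            nn.Linear(a, b, rng=rng, name=f"head{i}")
            for i, (a, b) in enumerate(zip(sizes, sizes[1:]))
        ]
        self.head_relus = [nn.ReLU() for _ in self.head[:-1]]

    def forward(self, fingerprints, vectors):
        f_img = self.resnet.features(fingerprints)
        f_vec = self.mlp.features(vectors)
        x = np.concatenate([f_img, f_vec], axis=1)
        for lin, act in zip(self.head[:-1], self.head_relus):
            x = act(lin(x))
        return self.head[-1](x)

    def backward(self, dout):
        d = self.head[-1].bprop(dout)
        for lin, act in zip(reversed(self.head[:-1]), reversed(self.head_relus)):
            d = lin.bprop(act.bprop(d))
        split = self.fusion.resnet_feature_dim
        d_img = self.resnet.backward_features(d[:, :split])
        d_vec = self.mlp.backward_features(d[:, split:])
        return d_img, d_vec


# ---------------------------------------------------------------------------
# builders & prediction
# ---------------------------------------------------------------------------


def build_resnet3d(config: ResNetConfig | None = None, *, seed: int = 0) -> ResNet3d:
    return ResNet3d(config or ResNetConfig(),
                    rng=np.random.default_rng(seed))


def build_mlp(config: MLPConfig | None = None, *, seed: int = 0) -> MLP:
    return MLP(config or MLPConfig(), rng=np.random.default_rng(seed))


def build_multimodal(resnet: ResNet3d, mlp: MLP,
                     fusion: FusionConfig | None = None, *,
                     seed: int = 0) -> MultimodalNet:
    """Fuse trained encoders (weights carried over by deep copy; the
    original Phase-I networks are left untouched) under a fresh head."""
    fusion = fusion or FusionConfig(
        resnet_feature_dim=resnet.config.feature_dim,
        mlp_feature_dim=mlp.config.feature_dim,
    )
    return MultimodalNet(copy.deepcopy(resnet), copy.deepcopy(mlp), fusion,
                         rng=np.random.default_rng(seed))


def _single_batch(fingerprint: FingerprintMap, connectivity: ConnectivityVector):
    fp = np.asarray(fingerprint.corr, dtype=nn.DTYPE)
    # (H,W,D,N) -> (1, N, H, W, D): region axis becomes the channel axis
    fp = np.moveaxis(fp, 3, 0)[None]
    vec = np.asarray(connectivity.values, dtype=nn.DTYPE)[None]
    return fp, vec


def predict(network, fingerprint: FingerprintMap | None = None,
            connectivity: ConnectivityVector | None = None) -> PredictionResult:
    """Run one subject through a network in evaluation mode."""
    network.eval()
    if isinstance(network, MultimodalNet):
        fp, vec = _single_batch(fingerprint, connectivity)
        logits = network(fp, vec)
    elif isinstance(network, ResNet3d):
        fp = np.moveaxis(np.asarray(fingerprint.corr, dtype=nn.DTYPE), 3, 0)[None]
        logits = network(fp)
    elif isinstance(network, MLP):
        logits = network(np.asarray(connectivity.values, dtype=nn.DTYPE)[None])
    else:
        raise ValidationError(f"unsupported network type {type(network).__name__}")
    probs = nn.softmax(logits.astype(np.float64))[0]
    cls = CLASS_NAMES[int(np.argmax(probs))]
    return PredictionResult(
        logits=tuple(float(v) for v in logits[0]),
        probabilities=tuple(float(p) for p in probs),
        predicted_class=cls,
    )


def parameter_count(network: nn.Module) -> int:
    return int(sum(p.data.size for p in network.parameters()))


# ---------------------------------------------------------------------------
# checkpoints: npz weights + embedded config JSON
# ---------------------------------------------------------------------------

def _config_payload(network) -> dict:
    if isinstance(network, ResNet3d):
        return {"kind": "resnet", "config": asdict(network.config)}
    if isinstance(network, MLP):
        return {"kind": "mlp", "config": asdict(network.config)}
    if isinstance(network, MultimodalNet):
        return {"kind": "multimodal",
                "resnet": asdict(network.resnet.config),
                "mlp": asdict(network.mlp.config),
                "fusion": asdict(network.fusion)}
    raise ValidationError(f"cannot checkpoint {type(network).__name__}")


def save_checkpoint(path: str | Path, network) -> Path:
    path = Path(path)
    state = network.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(_config_payload(network)).encode(), dtype=np.uint8)
    np.savez(path, **state)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def _tupled(d: dict) -> dict:
    return {k: tuple(tuple(x) if isinstance(x, list) else x for x in v)
            if isinstance(v, list) else v for k, v in d.items()}


def load_checkpoint(path: str | Path):
    path = Path(path)
    if not path.exists():
        raise CheckpointError(f"checkpoint not found: {path}")
    with np.load(path) as data:
        state = {k: data[k] for k in data.files}
    raw = state.pop("__config__", None)
    if raw is None:
        raise CheckpointError(f"{path}: missing embedded config")
    payload = json.loads(raw.tobytes().decode())
    kind = payload.get("kind")
    if kind == "resnet":
        net = build_resnet3d(ResNetConfig(**_tupled(payload["config"])))
    elif kind == "mlp":
        net = build_mlp(MLPConfig(**_tupled(payload["config"])))
    elif kind == "multimodal":
        resnet = build_resnet3d(ResNetConfig(**_tupled(payload["resnet"])))
        mlp = build_mlp(MLPConfig(**_tupled(payload["mlp"])))
        net = MultimodalNet(resnet, mlp, FusionConfig(**_tupled(payload["fusion"])),
                            rng=np.random.default_rng(0))
    else:
        raise CheckpointError(f"{path}: unknown model kind {kind!r}")
    net.load_state_dict(state)
    net.eval()
    return net
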