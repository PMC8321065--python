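"""Two-phase training protocol.

Phase I trains each encoder independently and from scratch: the 3D
ResNet on fingerprints (base LR 1e-2, 30 epochs, decayed x0.1 every 6)
and the MLP on connectivity vectors (1e-2, 50 epochs, decayed every 5).
Phase II builds the fused network from the Phase-I weights and trains it
end to end (full-scale defaults 1e-5, 30 epochs, decayed every 8).  All
phases use minibatch SGD (batch 8, momentum 0.9, no weight decay) with
softmax cross-entropy, per-epoch shuffling driven by the run seed, and
no validation split or early stopping — epoch counts are fixed.

The train/test split is drawn once, persisted, and reused by both phases
so no held-out subject ever touches a training step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .dataio import SubjectRecord
from .errors import DivergenceError, ValidationError
from .models import (FusionConfig, MLP, MultimodalNet, ResNet3d,
                     build_multimodal)


@dataclass
class TrainConfig:
    batch_size: int = 8
    momentum: float = 0.9
    base_lr: float = 1e-2
    epochs: int = 30
    lr_step: int = 6
    lr_gamma: float = 0.1
    seed: int = 0
    weight_decay: float = 0.0
    shuffle: bool = True

    def __post_init__(self):
        if self.base_lr < 0:
            raise ValidationError("base_lr must be >= 0")
        if not (0 < self.lr_gamma <= 1):
            raise ValidationError("lr_gamma must be in (0, 1]")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")


#: full-scale defaults for each phase
PHASE1_RESNET = TrainConfig(base_lr=1e-2, epochs=30, lr_step=6)
PHASE1_MLP = TrainConfig(base_lr=1e-2, epochs=50, lr_step=5)
PHASE2_MULTIMODAL = TrainConfig(base_lr=1e-5, epochs=30, lr_step=8)


def lr_at_epoch(base_lr: float, epoch: int, lr_step: int, lr_gamma: float) -> float:
    """Step decay: base_lr * lr_gamma ** floor(epoch / lr_step)."""
    if epoch < 0:
        raise ValidationError("epoch must be >= 0")
    return base_lr * lr_gamma ** (epoch // lr_step)


@dataclass
class SplitPlan:
    train_ids: list[str]
    test_ids: list[str]
    seed: int

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        payload = json.loads(Path(path).read_text())
        return cls(train_ids=list(payload["train_ids"]),
                   test_ids=list(payload["test_ids"]),
                   seed=int(payload["seed"]))


def split_dataset(records: list[SubjectRecord], n_train: int, seed: int,
                  stratified: bool = False) -> SplitPlan:
    """Uniformly random, seed-reproducible train/test partition."""
    n = len(records)
    if n_train >= n:
        raise ValidationError(f"n_train={n_train} must be < record count {n}")
    if n_train < 1:
        raise ValidationError("n_train must be >= 1")
    rng = np.random.default_rng(seed)
    ids = [r.subject_id for r in records]
    if stratified:
        train_idx: list[int] = []
        labels = np.array([r.label for r in records])
        frac = n_train / n
        remainders = []
        for lab in sorted(set(labels)):
            idx = np.flatnonzero(labels == lab)
            take = int(np.floor(len(idx) * frac))
            perm = rng.permutation(idx)
            train_idx.extend(perm[:take].tolist())
            remainders.extend(perm[take:].tolist())
        extra = n_train - len(train_idx)
        perm = rng.permutation(len(remainders))
        train_idx.extend(remainders[i] for i in perm[:extra])
        train_set = set(train_idx)
        train = [ids[i] for i in sorted(train_set)]
        test = [ids[i] for i in range(n) if i not in train_set]
    else:
        perm = rng.permutation(n)
        train = [ids[i] for i in sorted(perm[:n_train])]
        test = [ids[i] for i in sorted(perm[n_train:])]
    return SplitPlan(train_ids=train, test_ids=test, seed=seed)


@dataclass
class TrainResult:
    loss_history: list[float] = field(default_factory=list)
    accuracy_history: list[float] = field(default_factory=list)
    lr_history: list[float] = field(default_factory=list)


def _train_network(network: nn.Module, inputs: tuple[np.ndarray, ...],
                   labels: np.ndarray, config: TrainConfig) -> TrainResult:
    n = len(labels)
    if n == 0:
        raise ValidationError("empty training set")
    for arr in inputs:
        if len(arr) != n:
            raise ValidationError("inputs and labels must have equal length")
    rng = np.random.default_rng(config.seed)
    opt = nn.SGD(network.parameters(), lr=config.base_lr,
                 momentum=config.momentum, weight_decay=config.weight_decay)
    loss_fn = nn.SoftmaxCrossEntropy()
    result = TrainResult()
    network.train()
    for epoch in range(config.epochs):
        opt.lr = lr_at_epoch(config.base_lr, epoch, config.lr_step, config.lr_gamma)
        order = rng.permutation(n) if config.shuffle else np.arange(n)
        total_loss = 0.0
        correct = 0
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            xs = [np.ascontiguousarray(a[batch], dtype=nn.DTYPE) for a in inputs]
            ys = labels[batch]
            logits = network(*xs)
            loss = loss_fn.forward(logits, ys)
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            opt.zero_grad()
            network.backward(loss_fn.backward())
            opt.step()
            total_loss += loss * len(batch)
            correct += int((logits.argmax(axis=1) == ys).sum())
        result.loss_history.append(total_loss / n)
        result.accuracy_history.append(correct / n)
        result.lr_history.append(opt.lr)
    network.eval()
    return result


def train_phase1_resnet(network: ResNet3d, fingerprints: np.ndarray,
                        labels: np.ndarray,
                        config: TrainConfig | None = None
                        ) -> tuple[ResNet3d, TrainResult]:
    """Phase I for the fingerprint encoder.

    ``fingerprints``: (n_subjects, N_regions, H, W, D) array (region axis
    as channels); ``labels``: integer class targets.
    """
    config = config or PHASE1_RESNET
    result = _train_network(network, (fingerprints,), labels, config)
    return network, result


def train_phase1_mlp(network: MLP, vectors: np.ndarray, labels: np.ndarray,
                     config: TrainConfig | None = None) -> tuple[MLP, TrainResult]:
    """Phase I for the connectivity-vector encoder."""
    config = config or PHASE1_MLP
    result = _train_network(network, (vectors,), labels, config)
    return network, result


def train_phase2_multimodal(resnet: ResNet3d, mlp: MLP,
                            fusion: FusionConfig | None,
                            fingerprints: np.ndarray, vectors: np.ndarray,
                            labels: np.ndarray,
                            config: TrainConfig | None = None
                            ) -> tuple[MultimodalNet, TrainResult]:
    """Phase II: fuse the Phase-I encoders and train end to end.

    Encoder weights are carried over bit-exactly (the fused network holds
    deep copies, leaving the Phase-I networks untouched); the head is
    freshly initialised from the run seed.
    """
    config = config or PHASE2_MULTIMODAL
    fused = build_multimodal(resnet, mlp, fusion, seed=config.seed)
    result = _train_network(fused, (fingerprints, vectors), labels, config)
    return fused, result
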