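"""32-layer residual CNN for geographic-origin traceability images.

The network consumes 128x128x3 renderings of per-sample synchronous
2D-COS maps and predicts the origin class.  Architecture: a convolutional
stem (conv-BN-ReLU, stride 2, then 2x2 max pooling), four stages each
opened by one projection ("conv") residual block and followed by identity
residual blocks — 4 conv blocks and 11 identity blocks in total, two 3x3
convolutions per block — then global average pooling and one fully
connected layer.  Counting the stem, the 30 block convolutions, and the
fully connected head (projection shortcuts excluded by the usual residual
counting convention) gives 32 weighted layers.

Training follows the published protocol for this task: SGD, learning
rate 0.01, weight decay 0.0001, accuracy and cross-entropy curves logged
per epoch on the training and test partitions, a stratified 60/30/10
train/test/external split, and an exponential smoothing factor of 0.6
applied to the exported display curves only (never to the optimized
loss).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

__all__ = [
    "NetSpec",
    "TrainConfig",
    "SplitSpec",
    "TrainReport",
    "stratified_split",
    "build_network",
    "audit_weighted_layers",
    "train",
    "evaluate",
    "smooth_curve",
]


@dataclass
class NetSpec:
    """Architecture layout; block totals are fixed, widths are tunable."""

    input_size: int = 128
    in_channels: int = 3
    stem_channels: int = 8
    stage_widths: tuple[int, ...] = (8, 16, 32, 64)
    identity_per_stage: tuple[int, ...] = (2, 3, 3, 3)

    def __post_init__(self) -> None:
        if len(self.stage_widths) != len(self.identity_per_stage):
            raise ValueError("one identity count per stage required")
        if sum(self.identity_per_stage) != 11:
            raise ValueError(
                "the architecture uses 11 identity blocks + 4 conv blocks; "
                f"got {sum(self.identity_per_stage)} identity blocks"
            )
        if len(self.stage_widths) != 4:
            raise ValueError("the architecture uses exactly 4 stages")


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    weight_decay: float = 0.0001
    epochs: int = 100
    batch_size: int = 16
    momentum: float = 0.9
    seed: int = 0
    early_stop_loss: float = 1e-4  # stop once train cross-entropy falls below
    smoothing: float = 0.6  # display-curve smoothing only

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")


@dataclass
class SplitSpec:
    """Disjoint, exhaustive per-class 60/30/10 partition of sample indices."""

    train: np.ndarray
    test: np.ndarray
    external: np.ndarray
    fractions: tuple[float, float, float]
    seed: int

    def partition(self, name: str) -> np.ndarray:
        return {"train": self.train, "test": self.test, "external": self.external}[name]


@dataclass
class TrainReport:
    epochs_run: int
    train_acc: list[float] = field(default_factory=list)
    test_acc: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    test_loss: list[float] = field(default_factory=list)
    confusion: dict = field(default_factory=dict)  # partition -> matrix
    accuracy: dict = field(default_factory=dict)  # partition -> float

    def smoothed(self, which: str, factor: float = 0.6) -> list[float]:
        return smooth_curve(getattr(self, which), factor)


def smooth_curve(values: list[float], factor: float = 0.6) -> list[float]:
    """Exponential smoothing as used for exported display curves."""
    out: list[float] = []
    for v in values:
        out.append(v if not out else factor * out[-1] + (1 - factor) * v)
    return out


def stratified_split(
    labels: np.ndarray | list,
    fractions: tuple[float, float, float] = (0.6, 0.3, 0.1),
    seed: int = 0,
) -> SplitSpec:
    """Stratified train/test/external split by largest-remainder counts.

    Within each class, partition sizes are the largest-remainder
    apportionment of the fractions with tie priority train > test >
    external; assignment within a class is a seeded shuffle.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    parts: dict[str, list[np.ndarray]] = {"train": [], "test": [], "external": []}
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 3:
            raise ValueError(f"class {cls!r} has {idx.size} samples; need >= 3")
        rng.shuffle(idx)
        counts = _largest_remainder(idx.size, fractions)
        a, b, _ = counts
        parts["train"].append(idx[:a])
        parts["test"].append(idx[a : a + b])
        parts["external"].append(idx[a + b :])
    return SplitSpec(
        train=np.concatenate(parts["train"]),
        test=np.concatenate(parts["test"]),
        external=np.concatenate(parts["external"]),
        fractions=fractions,
        seed=seed,
    )


def _largest_remainder(n: int, fractions: tuple[float, float, float]) -> list[int]:
    quotas = [n * f for f in fractions]
    counts = [int(np.floor(q)) for q in quotas]
    # distribute leftover seats by remainder, priority train > test > external
    order = sorted(range(3), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in range(n - sum(counts)):
        counts[order[i % 3]] += 1
    return counts


class ResNet32:
    """The assembled network: callable layers plus an audit of its layout."""

    def __init__(self, spec: NetSpec, n_classes: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        layers: list[nn.Layer] = [
            nn.Conv2d(spec.in_channels, spec.stem_channels, 3, stride=2, rng=rng),
            nn.BatchNorm2d(spec.stem_channels),
            nn.ReLU(),
            nn.MaxPool2x2(),
        ]
        c_in = spec.stem_channels
        for s, (width, n_id) in enumerate(
            zip(spec.stage_widths, spec.identity_per_stage)
        ):
            stride = 1 if s == 0 else 2
            layers.append(nn.ResidualBlock(c_in, width, stride, rng))  # conv block
            for _ in range(n_id):
                layers.append(nn.ResidualBlock(width, width, 1, rng))
            c_in = width
        layers.append(nn.GlobalAvgPool())
        self.body = nn.Sequential(*layers)
        self.head = nn.Linear(c_in, n_classes, rng=rng)
        self.n_classes = n_classes

    def params(self) -> list[nn.Param]:
        return self.body.params() + self.head.params()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.head.forward(self.body.forward(x, train), train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.body.backward(self.head.backward(dout))


def build_network(spec: NetSpec | None = None, n_classes: int = 4, seed: int = 0) -> ResNet32:
    """Construct the residual network; the weighted-layer audit must be 32."""
    spec = spec or NetSpec()
    model = ResNet32(spec, n_classes, seed)
    n = audit_weighted_layers(model)
    if n != 32:
        raise ValueError(f"weighted-layer audit expected 32, found {n}")
    return model


def audit_weighted_layers(model: ResNet32) -> int:
    """Count weighted layers: all non-projection convolutions + the FC head."""

    def walk(layer) -> int:
        if isinstance(layer, nn.Conv2d):
            return 0 if layer.projection else 1
        if isinstance(layer, nn.Linear):
            return 1
        if isinstance(layer, nn.Sequential):
            return sum(walk(l) for l in layer.layers)
        if isinstance(layer, nn.ResidualBlock):
            n = walk(layer.main)
            if not layer.is_identity:
                n += walk(layer.short)
            return n
        return 0

    return walk(model.body) + walk(model.head)


def _forward_in_batches(model: ResNet32, x: np.ndarray, batch: int = 64) -> np.ndarray:
    outs = [model.forward(x[i : i + batch], train=False) for i in range(0, len(x), batch)]
    return np.concatenate(outs, axis=0)


def evaluate(
    model: ResNet32, images: np.ndarray, labels: np.ndarray, indices: np.ndarray
) -> tuple[float, np.ndarray, float]:
    """Accuracy, confusion matrix (rows = true class), and mean loss."""
    indices = np.asarray(indices)
    if indices.size == 0:
        raise ValueError("cannot evaluate an empty partition")
    logits = _forward_in_batches(model, images[indices])
    y = labels[indices]
    loss, _ = nn.cross_entropy(logits, y)
    pred = logits.argmax(axis=1)
    k = model.n_classes
    cm = np.zeros((k, k), dtype=int)
    np.add.at(cm, (y, pred), 1)
    return float(np.trace(cm) / cm.sum()), cm, loss


def train(
    model: ResNet32,
    images: np.ndarray,
    labels: np.ndarray,
    split: SplitSpec,
    config: TrainConfig | None = None,
) -> TrainReport:
    """Train on the train partition, logging both partitions per epoch.

    Minimizes unsmoothed softmax cross-entropy by SGD with momentum;
    stops early once the evaluated training loss drops below
    ``config.early_stop_loss``.  All randomness (batch order) comes from
    ``config.seed``.  Raises if the loss turns non-finite.
    """
    config = config or TrainConfig()
    images = np.ascontiguousarray(images, dtype=np.float32)
    labels = np.asarray(labels)
    for name in ("train", "test", "external"):
        part = split.partition(name)
        if np.unique(labels[part]).size < model.n_classes:
            raise ValueError(f"partition '{name}' is missing at least one class")
    opt = nn.SGD(
        model.params(),
        lr=config.learning_rate,
        momentum=config.momentum,
        weight_decay=config.weight_decay,
    )
    rng = np.random.default_rng(config.seed)
    report = TrainReport(epochs_run=0)
    tr = split.train
    for epoch in range(config.epochs):
        order = rng.permutation(tr.size)
        for start in range(0, tr.size, config.batch_size):
            idx = tr[order[start : start + config.batch_size]]
            logits = model.forward(images[idx], train=True)
            loss, dlogits = nn.cross_entropy(logits, labels[idx])
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged at epoch {epoch}")
            model.backward(dlogits.astype(np.float32))
            opt.step()
        tr_acc, _, tr_loss = evaluate(model, images, labels, split.train)
        te_acc, _, te_loss = evaluate(model, images, labels, split.test)
        report.train_acc.append(tr_acc)
        report.test_acc.append(te_acc)
        report.train_loss.append(tr_loss)
        report.test_loss.append(te_loss)
        report.epochs_run = epoch + 1
        if tr_loss < config.early_stop_loss:
            break
    for name in ("train", "test", "external"):
        acc, cm, _ = evaluate(model, images, labels, split.partition(name))
        report.accuracy[name] = acc
        report.confusion[name] = cm
    return report
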