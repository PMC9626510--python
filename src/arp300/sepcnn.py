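"""Separable 1D CNN for single-trial P300 scoring, plus the standard-CNN
comparator and the separable-convolution cost formulas.

Default architecture (input 200 samples x 30 channels):

    BatchNorm -> DepthConv1D(k=10, stride=6, pad=4) -> BatchNorm
    -> PointConv1D(4 kernels, k=1) -> Tanh -> Flatten(136)
    -> FullyConnected(136 -> 1) -> Sigmoid

The depthwise stage has exactly one kernel per input channel; the pointwise
stage mixes channels with size-1 kernels.  The network outputs the
probability that an epoch is a flash of the attended stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from . import nn
from .preprocess import EpochSet

__all__ = [
    "SepCNNConfig", "LayerDesc", "ModelSpec", "TrainHyper", "CostParams",
    "conv_output_len", "build_sepcnn", "build_standard_cnn",
    "separable_cost", "train", "score", "NetScorer",
]


def conv_output_len(in_len: int, kernel: int, stride: int, padding: int) -> int:
    """Temporal length of a 1D convolution output: floor((L + 2p - k)/s) + 1."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    span = in_len + 2 * padding - kernel
    if span < 0:
        raise ValueError(
            f"kernel {kernel} larger than padded input {in_len + 2 * padding}"
        )
    return span // stride + 1


@dataclass(frozen=True)
class SepCNNConfig:
    """Architecture hyper-parameters shared by both CNN variants."""

    input_len: int = 200
    n_channels: int = 30
    depth_kernel: int = 10
    stride: int = 6
    padding: int = 4
    n_pointwise: int = 4

    def __post_init__(self) -> None:
        for name in ("input_len", "n_channels", "depth_kernel", "stride", "n_pointwise"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.padding < 0:
            raise ValueError("padding must be >= 0")
        conv_output_len(self.input_len, self.depth_kernel, self.stride, self.padding)

    @property
    def out_len(self) -> int:
        """Temporal length after the strided convolution (34 with defaults)."""
        return conv_output_len(self.input_len, self.depth_kernel, self.stride, self.padding)

    @property
    def flatten_dim(self) -> int:
        """Width of the flattened feature vector (136 with defaults)."""
        return self.out_len * self.n_pointwise


@dataclass(frozen=True)
class LayerDesc:
    kind: str
    output_shape: tuple[int, ...]
    n_params: int = 0
    options: str = ""


@dataclass(frozen=True)
class ModelSpec:
    """Ordered layer descriptors for one CNN variant; purely declarative."""

    variant: str  # "sepcnn" | "standard_cnn"
    config: SepCNNConfig
    layers: tuple[LayerDesc, ...]

    @property
    def n_parameters(self) -> int:
        return sum(l.n_params for l in self.layers)

    def output_shapes(self) -> list[tuple[int, ...]]:
        return [l.output_shape for l in self.layers]


def build_sepcnn(config: SepCNNConfig = SepCNNConfig()) -> ModelSpec:
    """Describe the separable CNN: depthwise + pointwise convolution stack."""
    c = config
    H2, Nc, n = c.out_len, c.n_channels, c.n_pointwise
    layers = (
        LayerDesc("batchnorm", (c.input_len, Nc), 2 * Nc),
        LayerDesc("depthconv1d", (H2, Nc), Nc * c.depth_kernel + Nc,
                  f"stride={c.stride}, padding={c.padding}, groups={Nc}"),
        LayerDesc("batchnorm", (H2, Nc), 2 * Nc),
        LayerDesc("pointconv1d", (H2, n), n * Nc + n, "kernel=1"),
        LayerDesc("tanh", (H2, n)),
        LayerDesc("flatten", (H2 * n,)),
        LayerDesc("linear", (1,), H2 * n + 1),
        LayerDesc("sigmoid", (1,)),
    )
    return ModelSpec("sepcnn", c, layers)


def build_standard_cnn(config: SepCNNConfig = SepCNNConfig()) -> ModelSpec:
    """Describe the standard-CNN comparator: one dense convolution instead of
    the depthwise/pointwise pair, otherwise identical hyper-parameters."""
    c = config
    H2, Nc, n = c.out_len, c.n_channels, c.n_pointwise
    layers = (
        LayerDesc("batchnorm", (c.input_len, Nc), 2 * Nc),
        LayerDesc("stdconv1d", (H2, n), n * Nc * c.depth_kernel + n,
                  f"stride={c.stride}, padding={c.padding}"),
        LayerDesc("tanh", (H2, n)),
        LayerDesc("flatten", (H2 * n,)),
        LayerDesc("linear", (1,), H2 * n + 1),
        LayerDesc("sigmoid", (1,)),
    )
    return ModelSpec("standard_cnn", c, layers)


def instantiate(spec: ModelSpec, rng: np.random.Generator) -> nn.Sequential:
    """Materialise a ModelSpec as a trainable network (logit output; the
    sigmoid is fused into the loss)."""
    c = spec.config
    Nc, n = c.n_channels, c.n_pointwise
    if spec.variant == "sepcnn":
        layers = [
            nn.BatchNorm1d(Nc),
            nn.Conv1d(Nc, Nc, c.depth_kernel, c.stride, c.padding, groups=Nc, rng=rng),
            nn.BatchNorm1d(Nc),
            nn.Conv1d(Nc, n, 1, rng=rng),
            nn.Tanh(),
            nn.Flatten(),
            nn.Linear(c.flatten_dim, 1, rng=rng),
        ]
    elif spec.variant == "standard_cnn":
        layers = [
            nn.BatchNorm1d(Nc),
            nn.Conv1d(Nc, n, c.depth_kernel, c.stride, c.padding, rng=rng),
            nn.Tanh(),
            nn.Flatten(),
            nn.Linear(c.flatten_dim, 1, rng=rng),
        ]
    else:
        raise ValueError(f"unknown variant {spec.variant!r}")
    net = nn.Sequential(layers)
    assert net.n_parameters() == spec.n_parameters
    return net


@dataclass
class TrainHyper:
    """Training recipe (Adam + early stopping on validation loss)."""

    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 20
    pos_weight: float | None = None  # None -> n_negative / n_positive
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("learning_rate, batch_size and max_epochs must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")


@dataclass
class NetScorer:
    """Trained network exposing per-epoch target probabilities."""

    spec: ModelSpec
    net: nn.Sequential
    history: list[float] = field(default_factory=list)  # train loss per epoch
    val_history: list[float] = field(default_factory=list)

    def score(self, epochs: EpochSet) -> np.ndarray:
        return score(self, epochs)

    def fit(self, epochs: EpochSet) -> "NetScorer":  # TrainedScorer protocol
        raise RuntimeError("NetScorer is already fitted; use train()")


def _to_bcl(epochs: EpochSet, config: SepCNNConfig) -> np.ndarray:
    t = epochs.tensor
    if t.shape[1] != config.input_len or t.shape[2] != config.n_channels:
        raise ValueError(
            f"epoch tensor {t.shape[1]}x{t.shape[2]} does not match "
            f"model input {config.input_len}x{config.n_channels}"
        )
    return np.ascontiguousarray(t.transpose(0, 2, 1)).astype(np.float64)


def train(model_spec: ModelSpec, epoch_set: EpochSet, hyper: TrainHyper | None = None) -> NetScorer:
    """Fit a CNN variant by weighted binary cross-entropy.

    A stratified validation split drives early stopping; the best-validation
    weights are restored at the end.  Identical (data, hyper, seed) give a
    bit-identical scorer.
    """
    hyper = hyper or TrainHyper()
    X = _to_bcl(epoch_set, model_spec.config)
    y = np.asarray(epoch_set.labels).astype(float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("training set must contain both classes")
    pos_weight = hyper.pos_weight if hyper.pos_weight is not None else n_neg / n_pos

    rng = np.random.default_rng(hyper.seed)
    net = instantiate(model_spec, rng)

    # stratified validation split
    val_idx = []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_val = max(1, int(round(hyper.val_fraction * len(idx))))
        val_idx.append(idx[:n_val])
    val_idx = np.sort(np.concatenate(val_idx))
    train_mask = np.ones(len(y), bool)
    train_mask[val_idx] = False
    tr_idx = np.flatnonzero(train_mask)
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xva, yva = X[val_idx], y[val_idx]

    opt = nn.Adam(net, lr=hyper.learning_rate)
    scorer = NetScorer(model_spec, net)
    best_val = np.inf
    best_state = net.state()
    stale = 0
    for _ in range(hyper.max_epochs):
        order = rng.permutation(len(ytr))
        ep_loss = 0.0
        for start in range(0, len(order), hyper.batch_size):
            b = order[start:start + hyper.batch_size]
            z = net.forward(Xtr[b], train=True)
            loss, dz = nn.weighted_bce_with_logits(z, ytr[b], pos_weight)
            net.backward(dz.reshape(z.shape))
            opt.step()
            ep_loss += loss * len(b)
        scorer.history.append(ep_loss / len(ytr))
        zv = net.forward(Xva, train=False)
        val_loss, _ = nn.weighted_bce_with_logits(zv, yva, pos_weight)
        scorer.val_history.append(val_loss)
        if val_loss < best_val - 1e-7:
            best_val = val_loss
            best_state = net.state()
            stale = 0
        else:
            stale += 1
            if stale >= hyper.patience:
                break
    net.load_state(best_state)
    return scorer


def score(scorer: NetScorer, epoch_set: EpochSet) -> np.ndarray:
    """Per-epoch target probability in [0, 1] (deterministic inference mode)."""
    X = _to_bcl(epoch_set, scorer.spec.config)
    out = np.empty(len(X))
    for start in range(0, len(X), 512):  # bounded memory
        z = scorer.net.forward(X[start:start + 512], train=False)
        out[start:start + 512] = nn.sigmoid(z.ravel())
    return out


@dataclass(frozen=True)
class CostParams:
    """Computational cost of one separable vs one standard 1D convolution.

    Uses the stride-1, no-padding output length (H1 - h + 1), matching the
    closed-form cost expressions; the ratio is exactly 1/n + 1/h.
    """

    H1: int
    h: int
    n: int
    c_sep: int
    c_std: int
    ratio: Fraction


def separable_cost(H1: int, h: int, n: int) -> CostParams:
    """Evaluate the separable/standard convolution cost formulas.

    c_sep = h(H1 - h + 1) + n(H1 - h + 1); c_std = n h (H1 - h + 1);
    ratio = c_sep / c_std = 1/n + 1/h (exact rational arithmetic).
    """
    if h < 1 or n < 1:
        raise ValueError("h and n must be >= 1")
    if h >= H1:
        raise ValueError(f"kernel h={h} must be smaller than input length H1={H1}")
    span = H1 - h + 1
    c_sep = h * span + n * span
    c_std = n * h * span
    ratio = Fraction(c_sep, c_std)
    assert ratio == Fraction(1, n) + Fraction(1, h)
    return CostParams(H1=H1, h=h, n=n, c_sep=c_sep, c_std=c_std, ratio=ratio)
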