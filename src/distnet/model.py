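"""Residual network for distance-map prediction: build, train, predict.

The architecture is a stack of residual blocks (batch norm, ReLU, 3x3
convolution, dropout 0.3, ReLU, 3x3 convolution, identity skip) between an
entry 3x3 convolution and a 1x1 head convolution.  Three interchangeable
heads give the three formulations:

* ``contact`` — sigmoid output, binary cross-entropy against the <8 A
  contact map;
* ``binned``  — per-pair softmax over the variable-width distance bins,
  categorical cross-entropy;
* ``distance`` — ReLU output trained with log-cosh loss against the
  *reciprocated* true distance map, back-transformed to Angstrom at
  prediction time.

The network is fully convolutional: training runs on random 128x128 crops
(zero-padded by 5 on each side) while prediction runs at the full sequence
width without cropping.  The production-scale configuration uses 128 blocks;
desk-scale configurations with a few blocks and 8-16 filters train in
minutes on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import network as nn
from .binning import BinScheme, Distogram, build_bin_scheme
from .distmap import DistanceMap, distances_from_reciprocal, reciprocate
from .features import FeatureVolume, sample_crop_window, _crop_plane
from .losses import LossConfig, PROB_CLIP

__all__ = ["ModelConfig", "DistanceNetwork", "PredictionMap",
           "build_model", "train", "predict", "save_model", "load_model"]

HEADS = ("contact", "binned", "distance")


@dataclass
class ModelConfig:
    """Architecture hyper-parameters.

    ``num_blocks=128, filters=64`` is the production-scale configuration;
    the defaults here are a desk-scale network that exercises the identical
    architecture.
    """

    input_channels: int = 55
    num_blocks: int = 4
    filters: int = 16
    kernel: int = 3
    dropout_rate: float = 0.3
    head: str = "contact"
    num_bins: int = 0
    scale_K: float = 100.0
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.num_blocks < 1:
            raise ValueError("num_blocks must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.kernel % 2 != 1:
            raise ValueError("kernel must be odd")
        if self.head not in HEADS:
            raise ValueError(f"head must be one of {HEADS}")
        if self.head == "binned" and self.num_bins < 2:
            raise ValueError("binned head needs num_bins >= 2")

    @property
    def out_channels(self) -> int:
        return self.num_bins if self.head == "binned" else 1


@dataclass
class PredictionMap:
    """Model output for one target.

    ``kind='contact'``: L x L contact probabilities; ``kind='distance'``:
    L x L distances in Angstrom; ``kind='binned'``: L x L x B bin
    probabilities with the bin scheme attached.
    """

    kind: str
    values: np.ndarray
    scheme: BinScheme = None  # type: ignore[assignment]

    def as_distogram(self) -> Distogram:
        if self.kind != "binned":
            raise ValueError("not a binned prediction")
        return Distogram(probs=self.values, scheme=self.scheme)


class DistanceNetwork:
    """A residual network with one of the three output heads."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.rng = np.random.default_rng(seed)
        layers = [nn.Conv2D(config.input_channels, config.filters,
                            config.kernel, self.rng)]
        for _ in range(config.num_blocks):
            layers.append(nn.ResidualBlock(config.filters, config.kernel,
                                           config.dropout_rate, self.rng))
        layers.append(nn.Conv2D(config.filters, config.out_channels, 1,
                                self.rng))
        self.net = nn.Sequential(layers)
        self.scheme = build_bin_scheme() if config.head == "binned" else None

    # -- low level -----------------------------------------------------
    def forward_logits(self, x: np.ndarray, train: bool) -> np.ndarray:
        """(N, C, H, W) -> head pre-activations (N, out, H, W)."""
        return self.net.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        self.net.backward(dlogits)

    def parameters(self) -> list:
        return self.net.parameters()

    def num_params(self) -> int:
        return self.net.num_params()

    # -- inference -----------------------------------------------------
    def activate(self, logits: np.ndarray) -> np.ndarray:
        """Apply the head activation: sigmoid / softmax-over-bins / ReLU."""
        if self.config.head == "contact":
            return 1.0 / (1.0 + np.exp(-logits))
        if self.config.head == "binned":
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            return e / e.sum(axis=1, keepdims=True)
        return np.maximum(logits, 0.0)

    def predict(self, volume: FeatureVolume) -> PredictionMap:
        return predict(self, volume)


def build_model(config: ModelConfig, seed: int = 0) -> DistanceNetwork:
    """Instantiate a network (weights drawn from ``seed``)."""
    return DistanceNetwork(config, seed=seed)


def predict(model: DistanceNetwork, volume: FeatureVolume) -> PredictionMap:
    """Full-width prediction: no cropping, dropout off, output symmetrised.

    The raw head output P is replaced by (P + P^T) / 2, since distance and
    contact maps are symmetric.  The distance head's ReLU output lives in
    reciprocated label space and is back-transformed to Angstrom.
    """
    cfg = model.config
    if volume.num_channels != cfg.input_channels:
        raise ValueError(
            f"volume has {volume.num_channels} channels, "
            f"model expects {cfg.input_channels}")
    x = volume.values.transpose(2, 0, 1)[None]  # (1, C, L, L)
    out = model.activate(model.forward_logits(x, train=False))[0]
    if cfg.head == "binned":
        probs = out.transpose(1, 2, 0)  # (L, L, B)
        return PredictionMap(kind="binned",
                             values=(probs + probs.transpose(1, 0, 2)) / 2,
                             scheme=model.scheme)
    plane = (out[0] + out[0].T) / 2
    if cfg.head == "contact":
        return PredictionMap(kind="contact", values=plane)
    dist = distances_from_reciprocal(plane, K=cfg.scale_K, epsilon=cfg.epsilon,
                                     min_value=cfg.scale_K / 1000.0)
    return PredictionMap(kind="distance", values=dist)


# ---------------------------------------------------------------------------
# training


def _prepare_labels(dmap: DistanceMap, cfg: ModelConfig, scheme) -> np.ndarray:
    """Full-size training target plane for the configured head.

    contact: the true distances themselves (thresholded after cropping);
    binned: likewise (encoded after cropping); distance: the reciprocated
    map, computed before cropping so the diagonal-neighbour replacement sees
    the true diagonal.
    """
    if cfg.head == "distance":
        return reciprocate(dmap, K=cfg.scale_K, epsilon=cfg.epsilon).values
    return dmap.values


def _loss_and_grad(model: DistanceNetwork, logits: np.ndarray,
                   target: np.ndarray, mask: np.ndarray, scheme):
    """Masked mean loss and d(loss)/d(logits) for the configured head."""
    cfg = model.config
    n = max(int(mask.sum()), 1)
    if cfg.head == "contact":
        y = (target < 8.0).astype(float)
        p = model.activate(logits)[:, 0]
        pc = np.clip(p, PROB_CLIP, 1 - PROB_CLIP)
        loss = -(y * np.log(pc) + (1 - y) * np.log(1 - pc))
        dlogits = ((p - y) * mask / n)[:, None]
        return float((loss * mask).sum() / n), dlogits
    if cfg.head == "binned":
        bins = np.clip(np.searchsorted(scheme.edges, target, side="right") - 1,
                       0, scheme.num_bins - 1)
        p = model.activate(logits)
        N, B, H, W = p.shape
        onehot = np.eye(B)[bins].transpose(0, 3, 1, 2)
        picked = np.clip((p * onehot).sum(axis=1), PROB_CLIP, None)
        loss = (-np.log(picked) * mask).sum() / n
        dlogits = (p - onehot) * mask[:, None] / n
        return float(loss), dlogits
    # distance head: ReLU output vs reciprocated labels under log-cosh
    r = model.activate(logits)
    diff = r[:, 0] - target
    from .losses import logcosh
    loss = (logcosh(diff) * mask).sum() / n
    dlogits = (np.tanh(diff) * mask / n)[:, None] * (logits > 0)
    return float(loss), dlogits


def train(model: DistanceNetwork, dataset: list, loss_config: LossConfig = None,
          epochs: int = 10, crop: int = 128, pad: int = 5, seed: int = 0,
          lr: float = 1e-3, batch_size: int = 2):
    """Train on (FeatureVolume, DistanceMap) pairs with crop augmentation.

    Each epoch visits every target once in a shuffled order; each visit
    draws a fresh zero-padded random crop (features and labels share the
    window, padding is masked out of the loss).  Returns ``(model,
    history)`` with ``history['loss']`` holding the per-epoch mean training
    loss.  ``epochs=0`` returns the model untouched.
    """
    if not dataset:
        raise ValueError("empty dataset")
    cfg = model.config
    loss_config = loss_config or _default_loss(cfg)
    _check_loss_matches_head(cfg, loss_config)
    rng = np.random.default_rng(seed)
    scheme = model.scheme
    labels = [_prepare_labels(dmap, cfg, scheme) for _, dmap in dataset]
    masks = [np.asarray(dmap.mask, bool) for _, dmap in dataset]
    optimiser = nn.Adam(model.parameters(), lr=lr)
    history = {"loss": []}
    for _ in range(int(epochs)):
        order = rng.permutation(len(dataset))
        epoch_losses = []
        for start in range(0, len(order), batch_size):
            chunk = order[start:start + batch_size]
            xb, yb, mb = [], [], []
            for ti in chunk:
                volume, _ = dataset[ti]
                L = volume.length
                oi, oj = sample_crop_window(L, crop, pad, rng)
                xb.append(np.stack(
                    [_crop_plane(volume.values[:, :, c], oi, oj, crop, pad)
                     for c in range(volume.num_channels)]))
                yb.append(_crop_plane(labels[ti], oi, oj, crop, pad))
                mb.append(_crop_plane(masks[ti], oi, oj, crop, pad, fill=False))
            xb = np.stack(xb)
            yb = np.stack(yb)
            mb = np.stack(mb)
            if not mb.any():
                continue
            optimiser.zero_grad()
            logits = model.forward_logits(xb, train=True)
            loss, dlogits = _loss_and_grad(model, logits, yb, mb, scheme)
            model.backward(dlogits)
            optimiser.step()
            epoch_losses.append(loss)
        history["loss"].append(float(np.mean(epoch_losses)))
    return model, history


def _default_loss(cfg: ModelConfig) -> LossConfig:
    kind = {"contact": "contact-bce", "binned": "binned-ce",
            "distance": "reciprocal-logcosh"}[cfg.head]
    return LossConfig(kind=kind, K=cfg.scale_K, epsilon=cfg.epsilon)


def _check_loss_matches_head(cfg: ModelConfig, loss_config: LossConfig) -> None:
    expected = _default_loss(cfg).kind
    if loss_config.kind != expected:
        raise ValueError(
            f"head {cfg.head!r} trains with {expected!r}, "
            f"got {loss_config.kind!r}")


# ---------------------------------------------------------------------------
# persistence (flat npz of weights + JSON config)


def save_model(model: DistanceNetwork, path) -> None:
    arrays = {f"p{i}": p for i, (p, _) in enumerate(model.parameters())}
    bn_state = {}
    i = 0
    for layer in _iter_layers(model.net):
        if isinstance(layer, nn.BatchNorm2D):
            bn_state[f"rm{i}"] = layer.running_mean
            bn_state[f"rv{i}"] = layer.running_var
            i += 1
    np.savez(path, config=json.dumps(asdict(model.config)),
             **arrays, **bn_state)


def load_model(path) -> DistanceNetwork:
    data = np.load(path, allow_pickle=False)
    config = ModelConfig(**json.loads(str(data["config"])))
    model = DistanceNetwork(config, seed=0)
    for i, (p, _) in enumerate(model.parameters()):
        p[...] = data[f"p{i}"]
    i = 0
    for layer in _iter_layers(model.net):
        if isinstance(layer, nn.BatchNorm2D):
            layer.running_mean = data[f"rm{i}"]
            layer.running_var = data[f"rv{i}"]
            i += 1
    return model


def _iter_layers(seq):
    for layer in seq.layers:
        if isinstance(layer, nn.ResidualBlock):
            yield from layer.layers
        else:
            yield layer
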