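"""A small from-scratch CNN patch classifier trained with SGD in two phases.

Architecture: fixed 4x average-pool front end, four 3x3 convolution blocks
(8-16-32-32 channels, ReLU, 2x average pooling after the first three),
global average pooling, dropout on the pooled feature vector, and a 2-node
softmax output layer.  Everything is plain numpy; no GPU or deep-learning
framework is required, and the network accepts any patch size that survives
the pooling cascade (>= 32 px).

Training follows the two-phase schedule: first only the output head is
trained on frozen (randomly initialized) convolutional features, then all
weights are trained end to end.  Weights are initialized uniformly in
[-0.05, 0.05], the optimizer is SGD with momentum, and the returned state is
the checkpoint whose validation loss was smallest across all epochs of both
phases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..patches import NEGATIVE, POSITIVE, PatchRecord
from .base import PatchClassifier

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "SmallCNNClassifier", "train_small_cnn",
           "select_checkpoint"]


@dataclass(frozen=True)
class TrainConfig:
    """Two-phase SGD training schedule.

    The optimizer is fixed to stochastic gradient descent (with momentum);
    the checkpoint policy is fixed to minimum validation loss.
    """

    phase1_epochs: int = 10
    phase2_epochs: int = 10
    phase1_lr: float = 0.05
    phase2_lr: float = 0.01
    momentum: float = 0.9
    dropout: float = 0.5
    batch_size: int = 16
    grad_clip: float = 1.0      # global-norm clip on phase-2 conv gradients
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phase1_epochs < 1 or self.phase2_epochs < 0:
            raise ValueError("phase1_epochs >= 1, phase2_epochs >= 0 required")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.phase1_lr <= 0 or self.phase2_lr <= 0:
            raise ValueError("learning rates must be positive")


def select_checkpoint(validation_losses: Sequence[float]) -> int:
    """Index of the epoch whose validation loss is smallest (first argmin)."""
    if len(validation_losses) == 0:
        raise ValueError("no epochs recorded")
    return int(np.argmin(validation_losses))


# ---------------------------------------------------------------------------
# layers (N, C, H, W) tensors
# ---------------------------------------------------------------------------

class _Conv3x3:
    def __init__(self, rng: np.random.Generator, cin: int, cout: int):
        # He init keeps activation magnitude through the ReLU cascade; a
        # small uniform init attenuates features to ~0 after four layers.
        self.W = rng.normal(0.0, np.sqrt(2.0 / (cin * 9)), (cout, cin, 3, 3))
        self.b = np.zeros(cout)
        self._cols = None

    def forward(self, x: np.ndarray, keep_cache: bool) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        cols = sliding_window_view(xp, (3, 3), axis=(2, 3))
        self._cols = cols if keep_cache else None
        out = np.einsum("nchwij,ocij->nohw", cols, self.W, optimize=True)
        return out + self.b[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols = self._cols
        self.dW = np.einsum("nchwij,nohw->ocij", cols, dout, optimize=True)
        self.db = dout.sum(axis=(0, 2, 3))
        dp = np.pad(dout, ((0, 0), (0, 0), (1, 1), (1, 1)))
        dcols = sliding_window_view(dp, (3, 3), axis=(2, 3))
        Wf = self.W[:, :, ::-1, ::-1]
        return np.einsum("nohwij,ocij->nchw", dcols, Wf, optimize=True)

    params = ("W", "b")


class _AvgPool:
    def __init__(self, factor: int):
        self.f = factor

    def forward(self, x: np.ndarray, keep_cache: bool) -> np.ndarray:
        f = self.f
        n, c, h, w = x.shape
        h2, w2 = h // f, w // f
        if h2 == 0 or w2 == 0:
            raise ValueError("input too small for the pooling cascade")
        self._in_shape = x.shape
        x = x[:, :, :h2 * f, :w2 * f]
        return x.reshape(n, c, h2, f, w2, f).mean(axis=(3, 5))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        f = self.f
        n, c, h, w = self._in_shape
        dx = np.zeros(self._in_shape)
        up = np.repeat(np.repeat(dout, f, axis=2), f, axis=3) / (f * f)
        dx[:, :, :up.shape[2], :up.shape[3]] = up
        return dx

    params = ()


class _ReLU:
    def forward(self, x: np.ndarray, keep_cache: bool) -> np.ndarray:
        self._mask = x > 0 if keep_cache else None
        return np.maximum(x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    params = ()


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Net:
    """Conv feature extractor + GAP + dropout + 2-node softmax head."""

    N_FEATURES = 32

    def __init__(self, rng: np.random.Generator):
        self.front = _AvgPool(4)
        self.blocks = []
        for cin, cout, pool in ((3, 8, True), (8, 16, True),
                                (16, 32, True), (32, 32, False)):
            self.blocks.append(_Conv3x3(rng, cin, cout))
            self.blocks.append(_ReLU())
            if pool:
                self.blocks.append(_AvgPool(2))
        self.head_W = rng.uniform(-0.05, 0.05, (self.N_FEATURES, 2))
        self.head_b = np.zeros(2)
        # frozen feature standardization fitted on the training set; keeps
        # the head well-conditioned whatever the conv cascade's scale
        self.feat_mu = np.zeros(self.N_FEATURES)
        self.feat_sigma = np.ones(self.N_FEATURES)

    # -- feature extractor --------------------------------------------------

    def features(self, x: np.ndarray, keep_cache: bool = False) -> np.ndarray:
        """GAP feature vectors, shape (N, 32)."""
        h = self.front.forward(x, keep_cache)
        for layer in self.blocks:
            h = layer.forward(h, keep_cache)
        self._gap_in_shape = h.shape
        return h.mean(axis=(2, 3))

    def backward_features(self, dfeat: np.ndarray) -> None:
        n, c, hh, ww = self._gap_in_shape
        dh = np.broadcast_to(dfeat[:, :, None, None] / (hh * ww),
                             self._gap_in_shape).copy()
        for layer in reversed(self.blocks):
            dh = layer.backward(dh)
        self.front.backward(dh)

    # -- head ---------------------------------------------------------------

    def normalize_features(self, feats: np.ndarray) -> np.ndarray:
        return (feats - self.feat_mu) / self.feat_sigma

    def head_logits(self, feats: np.ndarray) -> np.ndarray:
        return self.normalize_features(feats) @ self.head_W + self.head_b

    def fit_feature_norm(self, feats: np.ndarray) -> None:
        self.feat_mu = feats.mean(axis=0)
        self.feat_sigma = feats.std(axis=0) + 1e-8

    # -- parameter plumbing -------------------------------------------------

    def conv_layers(self) -> list[_Conv3x3]:
        return [b for b in self.blocks if isinstance(b, _Conv3x3)]

    def get_state(self) -> list[np.ndarray]:
        state = []
        for conv in self.conv_layers():
            state += [conv.W.copy(), conv.b.copy()]
        state += [self.head_W.copy(), self.head_b.copy(),
                  self.feat_mu.copy(), self.feat_sigma.copy()]
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        it = iter(state)
        for conv in self.conv_layers():
            conv.W, conv.b = next(it).copy(), next(it).copy()
        self.head_W, self.head_b = next(it).copy(), next(it).copy()
        self.feat_mu, self.feat_sigma = next(it).copy(), next(it).copy()


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------

def _to_tensor(patches: Sequence[np.ndarray]) -> np.ndarray:
    arr = np.stack([np.asarray(p, dtype=np.float64) for p in patches])
    return arr.transpose(0, 3, 1, 2)  # NHWC -> NCHW


def _records_to_xy(records: Sequence[PatchRecord]) -> tuple[np.ndarray, np.ndarray]:
    labels = []
    for rec in records:
        if rec.label not in (POSITIVE, NEGATIVE):
            raise ValueError(
                f"record with label {rec.label!r} cannot be used for "
                "training/evaluation"
            )
        labels.append(1 if rec.label == POSITIVE else 0)
    return _to_tensor([r.pixels for r in records]), np.asarray(labels)


class SmallCNNClassifier(PatchClassifier):
    """Trained small CNN honoring the patch-classifier contract."""

    def __init__(self, net: _Net, validation_losses: list[float],
                 best_epoch: int):
        self.net = net
        self.validation_losses = validation_losses
        self.best_epoch = best_epoch

    def predict_proba(self, patch: np.ndarray, pos=None) -> float:
        return float(self.predict_proba_batch([patch])[0])

    def predict_proba_batch(self, patches: Sequence[np.ndarray]) -> np.ndarray:
        x = _to_tensor(patches)
        feats = self.net.features(x, keep_cache=False)
        return _softmax(self.net.head_logits(feats))[:, 1]

    def save(self, path) -> None:
        """Persist trained weights and the validation-loss history (.npz)."""
        state = self.net.get_state()
        arrays = {f"param_{i}": arr for i, arr in enumerate(state)}
        np.savez(path, n_params=len(state),
                 validation_losses=np.asarray(self.validation_losses),
                 best_epoch=self.best_epoch, **arrays)

    @classmethod
    def load(cls, path) -> "SmallCNNClassifier":
        data = np.load(path)
        net = _Net(np.random.default_rng(0))
        state = [data[f"param_{i}"] for i in range(int(data["n_params"]))]
        net.set_state(state)
        return cls(net, list(data["validation_losses"]),
                   int(data["best_epoch"]))


def _epoch_loss(net: _Net, x: np.ndarray, y: np.ndarray,
                batch: int = 64) -> float:
    losses = []
    for i in range(0, len(x), batch):
        feats = net.features(x[i:i + batch], keep_cache=False)
        p = _softmax(net.head_logits(feats))
        losses.append(-np.log(p[np.arange(len(p)), y[i:i + batch]] + 1e-12))
    return float(np.concatenate(losses).mean())


def train_small_cnn(train: Sequence[PatchRecord],
                    validation: Sequence[PatchRecord],
                    config: TrainConfig = TrainConfig()) -> SmallCNNClassifier:
    """Train the small CNN with the two-phase schedule.

    Phase 1 trains only the output head on frozen convolutional features;
    phase 2 trains all weights.  After every epoch the validation
    cross-entropy is recorded and the returned classifier carries the state
    with the smallest validation loss seen in either phase.

    Raises
    ------
    ValueError
        If the training set is single-class or the validation set is empty.
    """
    if not validation:
        raise ValueError("validation set must be non-empty")
    x_train, y_train = _records_to_xy(train)
    x_val, y_val = _records_to_xy(validation)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set must contain both classes")

    rng = np.random.default_rng(config.seed)
    net = _Net(rng)
    n = len(x_train)
    keep = 1.0 - config.dropout

    checkpoints: list[list[np.ndarray]] = []
    val_losses: list[float] = []

    def record_epoch() -> None:
        val_losses.append(_epoch_loss(net, x_val, y_val))
        checkpoints.append(net.get_state())

    def head_step(feats: np.ndarray, y: np.ndarray, lr: float,
                  vel: dict) -> np.ndarray:
        """One SGD step on the head; returns dL/dfeats (raw GAP features)."""
        z = net.normalize_features(feats)
        if config.dropout > 0:
            drop = (rng.random(z.shape) < keep) / keep
            z = z * drop
        else:
            drop = None
        p = _softmax(z @ net.head_W + net.head_b)
        dlogits = p.copy()
        dlogits[np.arange(len(y)), y] -= 1.0
        dlogits /= len(y)
        dW = z.T @ dlogits
        db = dlogits.sum(axis=0)
        dz = dlogits @ net.head_W.T
        if drop is not None:
            dz = dz * drop
        dfeats = dz / net.feat_sigma
        vel["W"] = config.momentum * vel.get("W", 0.0) - lr * dW
        vel["b"] = config.momentum * vel.get("b", 0.0) - lr * db
        net.head_W += vel["W"]
        net.head_b += vel["b"]
        return dfeats

    # ---- phase 1: head only, frozen conv features -------------------------
    feats_train = np.concatenate([
        net.features(x_train[i:i + 64]) for i in range(0, n, 64)
    ])
    net.fit_feature_norm(feats_train)
    vel: dict = {}
    for _ in range(config.phase1_epochs):
        order = rng.permutation(n)
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            head_step(feats_train[idx], y_train[idx], config.phase1_lr, vel)
        record_epoch()

    # ---- phase 2: all weights ---------------------------------------------
    convs = net.conv_layers()
    cvel = [{"W": 0.0, "b": 0.0} for _ in convs]
    vel = {}
    for _ in range(config.phase2_epochs):
        order = rng.permutation(n)
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            feats = net.features(x_train[idx], keep_cache=True)
            dfeats = head_step(feats, y_train[idx], config.phase2_lr, vel)
            net.backward_features(dfeats)
            gnorm = np.sqrt(sum(float((c.dW ** 2).sum() + (c.db ** 2).sum())
                                for c in convs))
            scale = min(1.0, config.grad_clip / (gnorm + 1e-12))
            for conv, v in zip(convs, cvel):
                v["W"] = config.momentum * v["W"] \
                    - config.phase2_lr * scale * conv.dW
                v["b"] = config.momentum * v["b"] \
                    - config.phase2_lr * scale * conv.db
                conv.W += v["W"]
                conv.b += v["b"]
        record_epoch()

    best = select_checkpoint(val_losses)
    net.set_state(checkpoints[best])
    logger.info("selected checkpoint from epoch %d/%d (val loss %.4f)",
                best + 1, len(val_losses), val_losses[best])
    return SmallCNNClassifier(net, val_losses, best)
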