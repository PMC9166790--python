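"""Trainable softmax readout: input -> 500 ReLU hidden units -> softmax.

Two weight matrices plus biases (80 x 500 x 20 in the reference
configuration, 50,520 parameters).  Training is online (batch of one
reservoir step) on next-symbol cross-entropy, by default with Adam.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from volamp.reservoir import Alphabet, MemristorReservoir, make_training_pairs

logger = logging.getLogger(__name__)

HIDDEN_UNITS = 500


@dataclass(frozen=True)
class TrainConfig:
    """Online training settings: 50 epochs of per-step cross-entropy updates."""

    epochs: int = 50
    learning_rate: float = 1e-3
    optimizer: str = "adam"  # "adam" or "sgd"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


class ReadoutNet:
    """Two-layer perceptron with ReLU hidden activation and softmax output."""

    def __init__(
        self,
        n_in: int,
        n_out: int,
        hidden: int = HIDDEN_UNITS,
        seed: int = 0,
        zero_init: bool = False,
    ):
        self.n_in = n_in
        self.n_out = n_out
        self.hidden = hidden
        rng = np.random.default_rng(seed)
        if zero_init:
            self.w1 = np.zeros((n_in, hidden))
            self.w2 = np.zeros((hidden, n_out))
        else:
            # fan-in scaled uniform init
            lim1 = math.sqrt(6.0 / n_in)
            lim2 = math.sqrt(6.0 / hidden)
            self.w1 = rng.uniform(-lim1, lim1, size=(n_in, hidden))
            self.w2 = rng.uniform(-lim2, lim2, size=(hidden, n_out))
        self.b1 = np.zeros(hidden)
        self.b2 = np.zeros(n_out)
        self._opt_state: dict | None = None

    def parameters(self) -> list[np.ndarray]:
        return [self.w1, self.b1, self.w2, self.b2]

    def count_parameters(self) -> int:
        """Total number of stored weight and bias scalars."""
        return sum(p.size for p in self.parameters())

    def forward(self, features: np.ndarray) -> np.ndarray:
        """Class probabilities for one feature vector."""
        x = np.asarray(features, dtype=float)
        if x.shape != (self.n_in,):
            raise ValueError(f"expected feature vector of length {self.n_in}, got {x.shape}")
        z1 = x @ self.w1 + self.b1
        h = np.maximum(z1, 0.0)
        z2 = h @ self.w2 + self.b2
        z2 = z2 - z2.max()  # shift-invariant, numerically safe
        e = np.exp(z2)
        return e / e.sum()

    def _gradients(
        self, features: np.ndarray, target_idx: int
    ) -> tuple[list[np.ndarray], float]:
        x = np.asarray(features, dtype=float)
        z1 = x @ self.w1 + self.b1
        h = np.maximum(z1, 0.0)
        z2 = h @ self.w2 + self.b2
        z2 = z2 - z2.max()
        e = np.exp(z2)
        p = e / e.sum()
        loss = -math.log(max(p[target_idx], 1e-300))
        dz2 = p.copy()
        dz2[target_idx] -= 1.0
        dw2 = np.outer(h, dz2)
        dh = self.w2 @ dz2
        dz1 = dh * (z1 > 0)
        dw1 = np.outer(x, dz1)
        return [dw1, dz1, dw2, dz2], loss

    def _apply_update(self, grads: list[np.ndarray], config: TrainConfig) -> None:
        params = self.parameters()
        if config.optimizer == "sgd":
            for p, g in zip(params, grads):
                p -= config.learning_rate * g
            return
        if self._opt_state is None:
            self._opt_state = {
                "t": 0,
                "m": [np.zeros_like(p) for p in params],
                "v": [np.zeros_like(p) for p in params],
            }
        st = self._opt_state
        st["t"] += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for i, (p, g) in enumerate(zip(params, grads)):
            st["m"][i] = b1 * st["m"][i] + (1 - b1) * g
            st["v"][i] = b2 * st["v"][i] + (1 - b2) * g * g
            mhat = st["m"][i] / (1 - b1 ** st["t"])
            vhat = st["v"][i] / (1 - b2 ** st["t"])
            p -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)


def forward(net: ReadoutNet, features: np.ndarray) -> np.ndarray:
    return net.forward(features)


def count_parameters(net: ReadoutNet) -> int:
    return net.count_parameters()


def train_step(
    net: ReadoutNet,
    features: np.ndarray,
    target: str,
    alphabet: Alphabet,
    config: TrainConfig,
) -> float:
    """One cross-entropy gradient step toward the target symbol; returns the loss."""
    idx = alphabet.index(target)
    grads, loss = net._gradients(features, idx)
    if not math.isfinite(loss):
        raise FloatingPointError("non-finite training loss")
    net._apply_update(grads, config)
    return loss


def fit(
    net: ReadoutNet,
    corpus: list[str],
    reservoir: MemristorReservoir,
    config: TrainConfig,
) -> list[float]:
    """Train on a corpus of sequences; returns the per-epoch mean loss history.

    For every sequence the reservoir is reset and streamed residue by
    residue; each (feature, next-symbol) pair — including the final
    (last residue, '@') pair — triggers one online update.  Group gains are
    frozen from a calibration pass over the corpus before the first epoch.
    """
    if not corpus:
        raise ValueError("corpus must be non-empty")
    if reservoir.group_gains is None:
        raw = []
        saved_scale = reservoir.feature_scale
        for seq in corpus:
            if seq:
                raw.append(reservoir.encode_sequence(seq))
        if not raw:
            raise ValueError("corpus contains only empty sequences")
        reservoir.feature_scale = saved_scale
        reservoir.calibrate(np.vstack(raw))

    history: list[float] = []
    for _ in range(config.epochs):
        losses: list[float] = []
        for seq in corpus:
            if not seq:
                logger.warning("skipping empty sequence in corpus")
                continue
            pairs = make_training_pairs(seq, reservoir.alphabet)
            reservoir.reset()
            for symbol, target in pairs:
                feats = reservoir.step(symbol)
                losses.append(train_step(net, feats, target, reservoir.alphabet, config))
        history.append(float(np.mean(losses)))
    return history
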