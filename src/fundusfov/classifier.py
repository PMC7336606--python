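"""Two-class DR classifier under a transfer-learning contract.

The classifier mirrors the structure of transfer learning with a large
pretrained CNN: a *frozen* convolutional feature-extractor stage followed by
a *trainable* two-class fully-connected + softmax head, retrained with
minibatch stochastic gradient descent (default minibatch 2, learning rate
1e-5, momentum 0.9).

The default desk-scale backend ("dog-head") uses an analytic frozen stage:
multi-scale difference-of-Gaussians (DoG) band-pass maps of the grayscale
image, rectified into on/off channels (bright-blob and dark-dot detectors at
three scales), plus a low-pass intensity map, each pooled globally over the
retina content region with mean/max/quantile statistics (the optic disc and
the image or mask rim are excluded from pooling).  These are the kinds of
features early CNN layers learn, and they respond to the structures that
distinguish
DR fundus images (bright exudate-like blobs, small dark dots) from healthy
ones — so a linear softmax head on top is trainable at desk scale with no
downloaded weights.  Backends are interchangeable behind the same
train/predict interface; evaluation code never inspects backend internals.

Class-probability convention: index 0 = No DR, index 1 = DR.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "TrainingConfig",
    "BinaryClassifier",
    "train",
    "predict_proba",
    "predict_many",
    "save_model",
    "load_model",
    "BACKENDS",
]

INPUT_SIDE = 227  # fixed classifier input: 227 x 227 x 3


@dataclass(frozen=True)
class TrainingConfig:
    """SGD hyperparameters for the trainable head.

    Defaults follow the transfer-learning recipe: minibatch size 2,
    learning rate 1e-5, momentum 0.9.  Training runs until the epoch-mean
    loss plateaus (relative improvement below ``plateau_tol`` for
    ``plateau_patience`` consecutive epochs) or ``max_epochs`` is reached.
    """

    minibatch_size: int = 2
    learning_rate: float = 1e-5
    momentum: float = 0.9
    max_epochs: int = 40
    plateau_tol: float = 1e-5
    plateau_patience: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.minibatch_size < 1:
            raise ValueError("minibatch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


# ---------------------------------------------------------------------------
# frozen feature stages

_DOG_SIGMAS = (1.0, 2.0, 4.0, 8.0)
_VALID_FLOOR = 0.05   # grayscale above this = retina content (not background)
_RIM_MARGIN = 20      # px eroded off the valid region before pooling
_DISC_FLOOR = 0.5     # grayscale of the optic-disc plateau and skirt
_DISC_MARGIN = 15     # px dilated around the disc before exclusion


def _dog_features(image: np.ndarray) -> np.ndarray:
    """Frozen DoG feature stage for one 227x227x3 uint8 image.

    Band-pass (difference-of-Gaussians) maps at three scales, rectified into
    on-centre (bright blob) and off-centre (dark dot / vessel) channels,
    plus a low-pass intensity map.  Statistics are pooled *globally* over
    the retina content region (grayscale above a floor, eroded by a rim
    margin so the retina/background or FOV-mask edge response is excluded,
    and with the optic disc — the brightest area — dilated and excluded, as
    lesion analysis conventionally does): mean, max and 99th percentile per
    map.  Global pooling over the disc-free content region makes the
    features tolerant to the recentring, rescaling and circular masking the
    FOV simulation applies, whose most drastic effect is how much of the
    frame the disc occupies.
    """
    g = image.astype(np.float64).mean(axis=2) / 255.0
    valid = g > _VALID_FLOOR
    if valid.sum() < 100:
        valid = np.ones_like(valid)
    dist = ndimage.distance_transform_edt(valid)
    core = dist > _RIM_MARGIN
    disc = g > _DISC_FLOOR
    if disc.any():
        disc = ndimage.binary_dilation(disc, iterations=_DISC_MARGIN)
    core = core & ~disc
    if core.sum() < 100:
        core = valid & ~disc
    if core.sum() < 100:
        core = valid
    blurs = [ndimage.gaussian_filter(g, s) for s in _DOG_SIGMAS]
    maps = []
    for a, b in zip(blurs[:-1], blurs[1:]):
        d = a - b
        maps.append(np.maximum(d, 0.0))   # on-centre: bright blobs
        maps.append(np.maximum(-d, 0.0))  # off-centre: dark dots / vessels
    maps.append(blurs[1])                 # low-pass intensity
    feats = []
    for m in maps:
        vals = m[core]
        feats.extend([vals.mean(), vals.max(), np.quantile(vals, 0.99)])
    return np.asarray(feats)


#: backend id -> (feature function, feature dimension probe done lazily)
BACKENDS = {
    "dog-head": _dog_features,
}


# ---------------------------------------------------------------------------
# model

@dataclass
class BinaryClassifier:
    """Frozen feature stage + fitted two-class softmax head."""

    backend: str
    weights: np.ndarray          # (2, d+1) including bias column
    feature_mean: np.ndarray     # (d,) standardisation of the frozen features
    feature_scale: np.ndarray    # (d,)
    config: TrainingConfig = field(default_factory=TrainingConfig)
    input_side: int = INPUT_SIDE

    def _features(self, image: np.ndarray) -> np.ndarray:
        img = np.asarray(image)
        if img.shape != (self.input_side, self.input_side, 3):
            raise ValueError(
                f"expected {self.input_side}x{self.input_side}x3 input, "
                f"got shape {img.shape}")
        phi = BACKENDS[self.backend](img)
        return (phi - self.feature_mean) / self.feature_scale


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _extract_all(images, backend: str) -> np.ndarray:
    fn = BACKENDS[backend]
    return np.stack([fn(np.asarray(im)) for im in images])


def train(images, labels, config: TrainingConfig | None = None,
          backend: str = "dog-head") -> BinaryClassifier:
    """Fit the two-class head on preprocessed images.

    Only the head parameters are updated; the feature stage is frozen.
    Training is a pure function of (images, labels, config): the minibatch
    order is drawn from a generator seeded by ``config.seed``, so identical
    inputs give identical parameters.

    Raises
    ------
    ValueError
        On image/label misalignment, wrong input size, or a single-class
        training set.
    """
    config = config or TrainingConfig()
    config.validate()
    labels = np.asarray(labels, dtype=int)
    if len(images) != len(labels):
        raise ValueError("images and labels must be aligned")
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("training set must contain both classes (labels 0 and 1)")
    for im in images:
        if np.asarray(im).shape != (INPUT_SIDE, INPUT_SIDE, 3):
            raise ValueError("all images must be 227x227x3")

    phi = _extract_all(images, backend)
    mean = phi.mean(axis=0)
    scale = phi.std(axis=0)
    # floor keeps near-constant training features from exploding under the
    # FOV-simulation domain shift (all features here are O(0.01..1))
    scale = np.maximum(scale, 1e-3)
    x = (phi - mean) / scale
    x = np.hstack([x, np.ones((len(x), 1))])  # bias column
    y = np.eye(2)[labels]

    rng = np.random.default_rng(config.seed)
    w = np.zeros((2, x.shape[1]))
    v = np.zeros_like(w)
    n = len(x)
    prev_loss = np.inf
    stall = 0
    for _ in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.minibatch_size):
            idx = order[start:start + config.minibatch_size]
            xb, yb = x[idx], y[idx]
            p = _softmax(xb @ w.T)
            epoch_loss += -np.sum(np.log(np.clip((p * yb).sum(axis=1),
                                                 1e-12, None)))
            grad = (p - yb).T @ xb / len(idx)
            v = config.momentum * v - config.learning_rate * grad
            w = w + v
        epoch_loss /= n
        if prev_loss - epoch_loss < config.plateau_tol * max(1.0, abs(prev_loss)):
            stall += 1
            if stall >= config.plateau_patience:
                break
        else:
            stall = 0
        prev_loss = epoch_loss

    return BinaryClassifier(backend=backend, weights=w, feature_mean=mean,
                            feature_scale=scale, config=config)


def predict_proba(model: BinaryClassifier, image: np.ndarray) -> np.ndarray:
    """Probability vector (p_noDR, p_DR) for one preprocessed image."""
    x = np.append(model._features(image), 1.0)
    return _softmax(model.weights @ x)


def predict_many(model: BinaryClassifier, images) -> np.ndarray:
    """(n, 2) probability matrix for a sequence of preprocessed images."""
    return np.stack([predict_proba(model, im) for im in images])


# ---------------------------------------------------------------------------
# serialization: single .npz file with a JSON metadata entry

def save_model(model: BinaryClassifier, path: str | Path) -> None:
    meta = {
        "backend": model.backend,
        "input_side": model.input_side,
        "config": {
            "minibatch_size": model.config.minibatch_size,
            "learning_rate": model.config.learning_rate,
            "momentum": model.config.momentum,
            "max_epochs": model.config.max_epochs,
            "plateau_tol": model.config.plateau_tol,
            "plateau_patience": model.config.plateau_patience,
            "seed": model.config.seed,
        },
    }
    buf = io.BytesIO()
    np.savez(buf, weights=model.weights, feature_mean=model.feature_mean,
             feature_scale=model.feature_scale,
             meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8))
    Path(path).write_bytes(buf.getvalue())


def load_model(path: str | Path) -> BinaryClassifier:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        return BinaryClassifier(
            backend=meta["backend"],
            weights=z["weights"],
            feature_mean=z["feature_mean"],
            feature_scale=z["feature_scale"],
            config=TrainingConfig(**meta["config"]),
            input_side=meta["input_side"],
        )
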