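"""Contrastive training of an image-embedding network on triplets.

The embedding model maps a 224 x 224 x 3 tiled-record spectrogram image
to an m-dimensional vector (default m = 256) and is trained to place each
anchor closer to its positive than to its negative by at least the margin,
minimizing the mean triplet hinge loss over seeded, shuffled batches of
16 triplets (48 images). Validation triplets come from held-out patients;
training stops at ``max_epochs`` or when validation loss has not improved
for ``patience`` epochs, and the weights of the best validation epoch are
restored. No normalization is applied to the embedding output by default.

The backbone is a deliberately small convolutional trunk (see
:mod:`.nnet`): the contrastive method is architecture-generic and the
desk-scale trunk trains in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, ParameterError
from .nnet import Adam, Dense, GlobalAvgPool, Sequential, build_trunk, images_to_batch
from .tripletgen import Triplet, TripletLossParams


@dataclass
class TrainConfig:
    batch_triplets: int = 16
    learning_rate: float = 1e-5
    max_epochs: int = 30
    patience: int = 5
    margin: float = 1.0
    seed: int = 0
    normalize_embedding: bool = False

    def __post_init__(self) -> None:
        if self.batch_triplets < 1:
            raise ParameterError("batch_triplets must be >= 1")
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be > 0")


class EmbeddingModel:
    """Trainable mapping from an image to an m-vector."""

    def __init__(self, m: int = 256, seed: int = 0, normalize: bool = False):
        self.m = m
        self.seed = seed
        self.normalize = normalize
        trunk, out_ch = build_trunk(seed)
        head = Sequential(
            [GlobalAvgPool(), Dense(out_ch, m, rng=np.random.default_rng(seed + 7))]
        )
        self.net = Sequential(trunk.layers + head.layers)

    def embed_batch(self, images: np.ndarray) -> np.ndarray:
        """Embed an NCHW batch; rows are m-vectors."""
        out = self.net.forward(images)
        if self.normalize:
            out = out / np.maximum(np.linalg.norm(out, axis=1, keepdims=True), 1e-12)
        return out

    def embed(self, image) -> np.ndarray:
        """Embed one (H, W, 3) image (or SpectrogramImage) to an m-vector."""
        from .spectro import SpectrogramImage

        pixels = image.pixels if isinstance(image, SpectrogramImage) else image
        pixels = np.asarray(pixels)
        if pixels.ndim != 3 or pixels.shape[2] != 3:
            raise ParameterError(f"expected an (H, W, 3) image, got {pixels.shape}")
        return self.embed_batch(images_to_batch([pixels]))[0]

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        arrays = {f"w{i}": p for i, p in enumerate(self.net.get_weights())}
        np.savez(path, m=self.m, seed=self.seed,
                 normalize=int(self.normalize), **arrays)

    @classmethod
    def load(cls, path) -> "EmbeddingModel":
        with np.load(path, allow_pickle=False) as z:
            model = cls(m=int(z["m"]), seed=int(z["seed"]),
                        normalize=bool(int(z["normalize"])))
            weights = [z[f"w{i}"]
                       for i in range(sum(1 for k in z if k.startswith("w")))]
        model.net.set_weights(weights)
        return model


def make_batches(
    triplets: list[Triplet], batch_triplets: int, seed: int
) -> list[list[Triplet]]:
    """Seeded shuffle into batches of ``batch_triplets`` triplets.

    Each batch references ``3 * batch_triplets`` record images (a final
    partial batch keeps the remainder).
    """
    if not triplets:
        raise DataError("no triplets to batch")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB1]))
    order = rng.permutation(len(triplets))
    return [
        [triplets[i] for i in order[a : a + batch_triplets]]
        for a in range(0, len(order), batch_triplets)
    ]


def _batch_loss_and_grad(model, batch, images, margin):
    """Mean hinge loss over a triplet batch and the gradient w.r.t. embeddings."""
    ids = [t.anchor for t in batch] + [t.positive for t in batch] + (
        [t.negative for t in batch]
    )
    x = images_to_batch([images[i] for i in ids])
    emb = model.net.forward(x)  # raw (unnormalized) output; see TrainConfig
    b = len(batch)
    ea, ep, en = emb[:b], emb[b : 2 * b], emb[2 * b :]
    dap = ea - ep
    dan = ea - en
    n_ap = np.linalg.norm(dap, axis=1)
    n_an = np.linalg.norm(dan, axis=1)
    losses = np.maximum(0.0, margin + n_ap - n_an)
    active = losses > 0

    grad = np.zeros_like(emb)
    uap = dap / np.maximum(n_ap, 1e-12)[:, None]
    uan = dan / np.maximum(n_an, 1e-12)[:, None]
    act = active[:, None] / b
    grad[:b] = (uap - uan) * act
    grad[b : 2 * b] = -uap * act
    grad[2 * b :] = uan * act
    return float(losses.mean()), x, grad


def evaluate_loss(
    model: EmbeddingModel,
    triplets: list[Triplet],
    images: dict[str, np.ndarray],
    margin: float,
    batch_size: int = 48,
) -> float:
    """Mean hinge loss of a triplet set under the current weights."""
    if not triplets:
        raise DataError("empty triplet set")
    total = 0.0
    for a in range(0, len(triplets), batch_size):
        chunk = triplets[a : a + batch_size]
        loss, _, _ = _batch_loss_and_grad(model, chunk, images, margin)
        total += loss * len(chunk)
    return total / len(triplets)


def triplet_accuracy(
    model: EmbeddingModel,
    triplets: list[Triplet],
    images: dict[str, np.ndarray],
) -> float:
    """Fraction of triplets with D(f(a), f(p)) < D(f(a), f(n))."""
    correct = 0
    for a in range(0, len(triplets), 48):
        chunk = triplets[a : a + 48]
        ids = [t.anchor for t in chunk] + [t.positive for t in chunk] + (
            [t.negative for t in chunk]
        )
        emb = model.embed_batch(images_to_batch([images[i] for i in ids]))
        b = len(chunk)
        n_ap = np.linalg.norm(emb[:b] - emb[b : 2 * b], axis=1)
        n_an = np.linalg.norm(emb[:b] - emb[2 * b :], axis=1)
        correct += int((n_ap < n_an).sum())
    return correct / len(triplets)


def train(
    model: EmbeddingModel,
    train_triplets: list[Triplet],
    val_triplets: list[Triplet],
    images: dict[str, np.ndarray],
    cfg: TrainConfig | None = None,
) -> tuple[EmbeddingModel, dict[str, list[float]]]:
    """Train the embedding with the triplet hinge loss.

    ``images`` maps record id to its tiled (H, W, 3) image; train and
    validation triplets should come from disjoint patients so validation
    loss measures generalization. Returns the model with the weights of
    the best validation epoch and the per-epoch loss history.
    """
    cfg = cfg or TrainConfig()
    if not val_triplets:
        raise DataError("empty validation set: early stopping undefined")
    if not train_triplets:
        raise DataError("no training triplets")
    TripletLossParams(cfg.margin)  # validates margin >= 0

    opt = Adam(model.net.params, lr=cfg.learning_rate)
    history: dict[str, list[float]] = {"train": [], "val": []}
    best_val = np.inf
    best_weights = model.net.get_weights()
    stale = 0
    for epoch in range(cfg.max_epochs):
        batches = make_batches(train_triplets, cfg.batch_triplets,
                               seed=cfg.seed + epoch)
        epoch_loss = 0.0
        for batch in batches:
            loss, x, gemb = _batch_loss_and_grad(model, batch, images, cfg.margin)
            epoch_loss += loss * len(batch)
            model.net.backward(gemb)
            opt.step(model.net.grads)
        history["train"].append(epoch_loss / len(train_triplets))
        val_loss = evaluate_loss(model, val_triplets, images, cfg.margin)
        history["val"].append(val_loss)
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_weights = model.net.get_weights()
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    model.net.set_weights(best_weights)
    return model, history
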