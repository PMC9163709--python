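"""Feature extraction from spectrogram images and raw channels.

Two families of record-level features feed the clustering and retrieval
stages:

* convolutional feature maps — a backend network maps each channel's
  224 x 224 x 3 spectrogram image to a C x H x W feature map taken from
  its final retained convolutional layer; the four channel maps are
  flattened and concatenated in channel order with zero-fill for missing
  channels;
* a hand-engineered spectral baseline — periodogram power in seven
  frequency bands (0-4, 4-8, 8-12, 12-25, 25-50, 50-125, 0-125 Hz) per
  channel, 28 values per record.

Backends are pluggable and share the C x H x W output contract:
``random_init`` (seeded, untrained), ``classifier_surrogate`` (trained
in-package on labelled synthetic images to separate seizure from
non-seizure spectrograms, then used frozen as an extractor) and
``generic_pretrained`` (fixed weights loaded from disk). ``truncate_layers``
removes convolution blocks from the end of the trunk, exposing an
earlier, spatially larger map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import periodogram

from .errors import ContractError, ParameterError
from .nnet import (
    Adam,
    Dense,
    GlobalAvgPool,
    Sequential,
    TRUNK_BLOCKS,
    build_trunk,
    images_to_batch,
    softmax_cross_entropy,
)
from .records import FS, N_CHANNELS, IEEGRecord
from .spectro import SpectrogramImage

#: half-open frequency bands of the spectral baseline, Hz
SPECTRAL_BANDS = (
    (0.0, 4.0),
    (4.0, 8.0),
    (8.0, 12.0),
    (12.0, 25.0),
    (25.0, 50.0),
    (50.0, 125.0),
    (0.0, 125.0),
)

BACKEND_KINDS = ("generic_pretrained", "classifier_surrogate", "random_init")


@dataclass
class FeatureBackend:
    """A convolutional feature extractor honouring the C x H x W contract."""

    name: str
    kind: str
    trunk: Sequential
    out_channels: int
    truncate_layers: int = 0
    seed: int = 0
    head: Sequential | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in BACKEND_KINDS:
            raise ParameterError(f"unknown backend kind {self.kind!r}")
        if self.truncate_layers < 0:
            raise ParameterError("truncate_layers must be >= 0")

    @property
    def map_shape(self) -> tuple[int, int, int]:
        """(C, H, W) of the produced feature map for a 224 px input."""
        probe = np.zeros((1, 3, 224, 224))
        out = self.trunk.forward(probe)
        return tuple(out.shape[1:])

    @property
    def feature_length(self) -> int:
        c, h, w = self.map_shape
        return c * h * w


def make_backend(
    kind: str,
    seed: int = 0,
    truncate_layers: int = 0,
    weights_path=None,
    name: str | None = None,
) -> FeatureBackend:
    """Instantiate a backend.

    ``truncate_layers`` removes that many convolution blocks from the end
    of the trunk. ``generic_pretrained`` requires ``weights_path`` (an
    ``.npz`` saved by :func:`save_backend`); the surrogate classifier is
    produced by :func:`train_surrogate_classifier` instead.
    """
    if kind == "classifier_surrogate":
        raise ParameterError(
            "use train_surrogate_classifier() or load_backend() for the "
            "surrogate backend"
        )
    n_blocks = len(TRUNK_BLOCKS) - truncate_layers
    if n_blocks < 1:
        raise ParameterError(
            f"truncate_layers={truncate_layers} removes every block"
        )
    trunk, out_ch = build_trunk(seed, n_blocks)
    backend = FeatureBackend(
        name=name or f"{kind}-s{seed}",
        kind=kind,
        trunk=trunk,
        out_channels=out_ch,
        truncate_layers=truncate_layers,
        seed=seed,
    )
    if kind == "generic_pretrained":
        if weights_path is None:
            raise ParameterError(
                "generic_pretrained needs weights_path: no pretrained "
                "weights ship with the package"
            )
        loaded = load_backend(weights_path)
        return loaded
    return backend


def extract_channel_features(
    image: SpectrogramImage | np.ndarray, backend: FeatureBackend
) -> np.ndarray:
    """Feature map (C, H, W) of one channel image."""
    pixels = image.pixels if isinstance(image, SpectrogramImage) else image
    pixels = np.asarray(pixels)
    if pixels.shape != (224, 224, 3):
        raise ParameterError(
            f"backend expects a 224x224x3 image, got {pixels.shape}"
        )
    batch = images_to_batch([pixels])
    return backend.trunk.forward(batch)[0]


def combine_record_features(
    maps: list[np.ndarray | None], missing: set[int] | None = None
) -> np.ndarray:
    """Concatenate per-channel maps into one record-level vector.

    ``maps`` holds one C x H x W map per channel slot (``None`` where the
    channel is absent); absent slots contribute a zero block of the same
    length, so the output length is always ``4 * C * H * W``.
    """
    missing = set(missing or ())
    shapes = {m.shape for i, m in enumerate(maps) if m is not None and i not in missing}
    if not shapes:
        raise ContractError("no present channel maps to combine")
    if len(shapes) > 1:
        raise ContractError(f"inconsistent map shapes: {sorted(shapes)}")
    (shape,) = shapes
    block = int(np.prod(shape))
    out = np.zeros(N_CHANNELS * block)
    for i in range(N_CHANNELS):
        m = maps[i] if i < len(maps) else None
        if i in missing or m is None:
            continue
        out[i * block : (i + 1) * block] = np.asarray(m).ravel()
    return out


def record_features(
    record: IEEGRecord, backend: FeatureBackend, cfg=None
) -> np.ndarray:
    """Render each present channel and return the combined feature vector."""
    from .spectro import render_record_channels

    images = render_record_channels(record, cfg)
    maps = [
        None if im is None else extract_channel_features(im, backend)
        for im in images
    ]
    return combine_record_features(maps, set(record.missing_channels))


def spectral_power_features(record: IEEGRecord) -> np.ndarray:
    """28 spectral-power features: 7 band powers x 4 channels.

    Band power is the sum of the plain (rectangular-window) periodogram
    over half-open bands [lo, hi); missing channels contribute zeros.
    """
    out = np.zeros(N_CHANNELS * len(SPECTRAL_BANDS))
    for i, ch in enumerate(record.channels):
        if ch is None:
            continue
        freqs, pxx = periodogram(ch, fs=FS, window="boxcar")
        for j, (lo, hi) in enumerate(SPECTRAL_BANDS):
            sel = (freqs >= lo) & (freqs < hi)
            out[i * len(SPECTRAL_BANDS) + j] = pxx[sel].sum()
    return out


# ---------------------------------------------------------------------------
# surrogate classifier


@dataclass
class SurrogateTrainConfig:
    epochs: int = 8
    batch_size: int = 32
    learning_rate: float = 1e-3
    holdout_fraction: float = 0.25
    seed: int = 0


def train_surrogate_classifier(
    images: list[np.ndarray], labels: list[int] | np.ndarray,
    cfg: SurrogateTrainConfig | None = None,
) -> tuple[FeatureBackend, float]:
    """Train a small convolutional classifier on labelled images.

    The trunk's final convolutional map is the extraction contract; the
    classification head is kept only for training and accuracy reporting.
    Returns the frozen backend and its held-out accuracy.
    """
    cfg = cfg or SurrogateTrainConfig()
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ParameterError("surrogate training needs >=2 classes")
    remap = {c: i for i, c in enumerate(classes)}
    y = np.array([remap[c] for c in labels])
    x = images_to_batch(
        [im.pixels if isinstance(im, SpectrogramImage) else im for im in images]
    )

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5C]))
    order = rng.permutation(len(y))
    n_hold = max(1, int(round(cfg.holdout_fraction * len(y))))
    hold, tr = order[:n_hold], order[n_hold:]
    if tr.size == 0:
        raise ParameterError("not enough images to hold out a validation split")

    trunk, out_ch = build_trunk(cfg.seed)
    head = Sequential([GlobalAvgPool(), Dense(out_ch, classes.size,
                                              rng=np.random.default_rng(cfg.seed + 1))])
    params = trunk.params + head.params
    grads = trunk.grads + head.grads
    opt = Adam(params, lr=cfg.learning_rate)

    for _ in range(cfg.epochs):
        perm = rng.permutation(tr)
        for a in range(0, perm.size, cfg.batch_size):
            idx = perm[a : a + cfg.batch_size]
            fmap = trunk.forward(x[idx])
            logits = head.forward(fmap)
            _, dlogits = softmax_cross_entropy(logits, y[idx])
            trunk.backward(head.backward(dlogits))
            opt.step(grads)

    logits = head.forward(trunk.forward(x[hold]))
    accuracy = float((logits.argmax(axis=1) == y[hold]).mean())
    backend = FeatureBackend(
        name=f"surrogate-s{cfg.seed}",
        kind="classifier_surrogate",
        trunk=trunk,
        out_channels=out_ch,
        seed=cfg.seed,
        head=head,
    )
    return backend, accuracy


# ---------------------------------------------------------------------------
# persistence


def save_backend(backend: FeatureBackend, path) -> None:
    """Save a backend's weights and construction parameters to .npz."""
    arrays = {f"w{i}": p for i, p in enumerate(backend.trunk.get_weights())}
    np.savez(
        path,
        kind=backend.kind,
        name=backend.name,
        seed=backend.seed,
        truncate_layers=backend.truncate_layers,
        **arrays,
    )


def load_backend(path) -> FeatureBackend:
    """Reconstruct a backend saved by :func:`save_backend`."""
    with np.load(path, allow_pickle=False) as z:
        kind = str(z["kind"])
        name = str(z["name"])
        seed = int(z["seed"])
        trunc = int(z["truncate_layers"])
        weights = [z[f"w{i}"] for i in range(len([k for k in z if k.startswith("w")]))]
    trunk, out_ch = build_trunk(seed, len(TRUNK_BLOCKS) - trunc)
    trunk.set_weights(weights)
    return FeatureBackend(
        name=name, kind=kind, trunk=trunk, out_channels=out_ch,
        truncate_layers=trunc, seed=seed,
    )


def save_features(ids: list[tuple[str, str]], matrix: np.ndarray, path) -> None:
    """Persist a feature matrix keyed by (patient_id, record_id) as Parquet."""
    import pandas as pd

    df = pd.DataFrame(
        matrix,
        index=pd.MultiIndex.from_tuples(ids, names=["patient_id", "record_id"]),
    )
    df.columns = [f"f{i}" for i in range(matrix.shape[1])]
    df.to_parquet(path)


def load_features(path) -> tuple[list[tuple[str, str]], np.ndarray]:
    import pandas as pd

    df = pd.read_parquet(path)
    return list(df.index), df.to_numpy()
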