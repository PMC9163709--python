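"""Fixed-size colour spectrogram images of iEEG channels.

Each channel is rendered as a 224 x 224 x 3 image: short-time Fourier
power (Hann window of 256 samples, step 128) over 0-125 Hz, converted to
decibels, clipped to a per-image percentile range, normalized to [0, 1],
mapped through a fixed 256-entry jet lookup table and bilinearly resized.
For the contrastive method the four channels are rendered at 112 px and
tiled 2 x 2 into one record-level image; missing channels become black
tiles.

The jet lookup table is computed in-package from the classic
piecewise-linear segment definition so rendered images are bit-stable
and independent of any plotting library's colormap internals.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.signal import spectrogram as _scipy_spectrogram

from .errors import DataError, ParameterError
from .records import FS, N_CHANNELS, IEEGRecord


@dataclass
class SpectrogramConfig:
    window: int = 256          # STFT window length, samples
    step: int = 128            # hop between windows, samples
    fmax: float = 125.0        # top of the displayed frequency axis, Hz
    out_size: int = 224        # output image side, pixels
    colormap: str = "jet"
    scale: str = "db"          # "db" or "linear"
    clip: tuple[float, float] = (1.0, 99.0)  # per-image percentile clip

    def __post_init__(self) -> None:
        if self.step > self.window:
            raise ParameterError("step must be <= window")
        if self.fmax > FS / 2:
            raise ParameterError(f"fmax must be <= {FS / 2} Hz (Nyquist)")
        if self.scale not in ("db", "linear"):
            raise ParameterError(f"unknown scale {self.scale!r}")
        if self.colormap != "jet":
            raise ParameterError("only the fixed jet colormap is shipped")


@dataclass
class SpectrogramImage:
    """Rendered image plus its provenance."""

    pixels: np.ndarray                      # out_size x out_size x 3 in [0,1]
    source: tuple[str, str, str]            # (patient_id, record_id, channel)


# classic jet: piecewise-linear ramps per colour channel over [0, 1]
_JET_SEGMENTS = {
    "red": [(0.0, 0.0), (0.35, 0.0), (0.66, 1.0), (0.89, 1.0), (1.0, 0.5)],
    "green": [(0.0, 0.0), (0.125, 0.0), (0.375, 1.0), (0.64, 1.0), (0.91, 0.0), (1.0, 0.0)],
    "blue": [(0.0, 0.5), (0.11, 1.0), (0.34, 1.0), (0.65, 0.0), (1.0, 0.0)],
}


@lru_cache(maxsize=None)
def jet_lut(n: int = 256) -> np.ndarray:
    """The fixed n-entry jet lookup table, shape (n, 3), values in [0, 1]."""
    x = np.linspace(0.0, 1.0, n)
    lut = np.empty((n, 3))
    for j, name in enumerate(("red", "green", "blue")):
        pts = np.array(_JET_SEGMENTS[name])
        lut[:, j] = np.interp(x, pts[:, 0], pts[:, 1])
    return lut


def stft_power(samples: np.ndarray, cfg: SpectrogramConfig | None = None):
    """Short-time Fourier power of one channel.

    Returns ``(freqs, power)`` where ``power`` has ``window/2 + 1``
    frequency rows (ascending, 0 to Nyquist, truncated at ``fmax``) and
    ``floor((N - window) / step) + 1`` time columns.
    """
    cfg = cfg or SpectrogramConfig()
    samples = np.asarray(samples, dtype=np.float64)
    if samples.size < cfg.window:
        raise DataError(
            f"need at least {cfg.window} samples for one STFT window, "
            f"got {samples.size}"
        )
    freqs, _, sxx = _scipy_spectrogram(
        samples,
        fs=FS,
        window="hann",
        nperseg=cfg.window,
        noverlap=cfg.window - cfg.step,
        detrend=False,
        scaling="density",
        mode="psd",
    )
    keep = freqs <= cfg.fmax + 1e-9
    return freqs[keep], sxx[keep]


def _resize_bilinear(img: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    from skimage.transform import resize

    return resize(
        img, out_hw, order=1, mode="edge", anti_aliasing=False,
        preserve_range=True,
    )


def render_channel(
    samples: np.ndarray,
    cfg: SpectrogramConfig | None = None,
    source: tuple[str, str, str] = ("", "", ""),
    out_size: int | None = None,
) -> SpectrogramImage:
    """Render one channel to a colour spectrogram image.

    Power is mapped to decibels (unless ``scale="linear"``), clipped to
    the per-image ``clip`` percentile range, normalized to [0, 1], sent
    through the jet lookup table and bilinearly resized. Low frequencies
    sit at the bottom row of the image. A constant signal yields a
    uniform image at the colormap's low endpoint.
    """
    cfg = cfg or SpectrogramConfig()
    size = out_size or cfg.out_size
    _, power = stft_power(samples, cfg)

    if cfg.scale == "db":
        z = 10.0 * np.log10(power + 1e-20)
    else:
        z = power
    lo, hi = np.percentile(z, cfg.clip)
    if hi - lo < 1e-12:
        norm = np.zeros_like(z)
    else:
        norm = np.clip((z - lo) / (hi - lo), 0.0, 1.0)

    norm = _resize_bilinear(norm, (size, size))
    lut = jet_lut()
    idx = np.clip(np.round(norm * (len(lut) - 1)).astype(int), 0, len(lut) - 1)
    rgb = lut[idx]
    rgb = rgb[::-1]  # low frequency at the bottom row
    return SpectrogramImage(pixels=np.ascontiguousarray(rgb), source=source)


def render_tiled(
    record: IEEGRecord, cfg: SpectrogramConfig | None = None
) -> SpectrogramImage:
    """Render a whole record as a 2 x 2 tiled image.

    Channels 1-4 are rendered at half resolution and placed row-major
    (ch1 top-left, ch2 top-right, ch3 bottom-left, ch4 bottom-right);
    absent channels become all-zero (black) tiles.
    """
    cfg = cfg or SpectrogramConfig()
    half = cfg.out_size // 2
    canvas = np.zeros((cfg.out_size, cfg.out_size, 3))
    for i in range(N_CHANNELS):
        ch = record.channels[i]
        if ch is None:
            continue
        tile = render_channel(
            ch, cfg, (record.patient_id, record.record_id, f"ch{i + 1}"),
            out_size=half,
        ).pixels
        r, c = divmod(i, 2)
        canvas[r * half : (r + 1) * half, c * half : (c + 1) * half] = tile
    return SpectrogramImage(
        pixels=canvas, source=(record.patient_id, record.record_id, "tiled")
    )


def render_record_channels(
    record: IEEGRecord, cfg: SpectrogramConfig | None = None
) -> list[SpectrogramImage | None]:
    """Per-channel images for a record; ``None`` for absent channels."""
    cfg = cfg or SpectrogramConfig()
    out: list[SpectrogramImage | None] = []
    for i in range(N_CHANNELS):
        ch = record.channels[i]
        if ch is None:
            out.append(None)
        else:
            out.append(
                render_channel(
                    ch, cfg,
                    (record.patient_id, record.record_id, f"ch{i + 1}"),
                )
            )
    return out


def save_png(image: SpectrogramImage, path) -> None:
    """Export an image for visual inspection."""
    import imageio.v3 as iio

    iio.imwrite(path, (image.pixels * 255).astype(np.uint8))
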