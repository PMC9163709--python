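"""Length normalization and stimulation-artifact rejection.

Stored iEEG events vary from 30 to 240 s; downstream spectrogram images
must come from records of similar length. Records shorter than 80 s are
padded to 90 s by duplicating a stretch from the beginning of the record
and concatenating it onto the beginning; records longer than 100 s are
cropped to the window from 30 s before to 60 s after the storage trigger.
Records already in the 80-100 s range pass through unchanged (a stricter
``crop_above_target`` switch crops anything above 90 s instead).

Stimulation artifact — brief rail-to-rail device pulses — is detected by
a per-channel slew-rate threshold and blanked by linear interpolation.
The detector is a deliberately simple robust-threshold stand-in: the
device pulses it targets are orders of magnitude steeper than
physiological activity, so a median-absolute-deviation rule on the
differenced signal suffices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DataError, ParameterError
from .records import FS, IEEGRecord, n_samples


@dataclass
class PreprocessConfig:
    """Length-normalization and artifact-rejection settings (seconds)."""

    target_s: float = 90.0
    short_threshold_s: float = 80.0
    long_threshold_s: float = 100.0
    pre_trigger_s: float = 30.0
    post_trigger_s: float = 60.0
    artifact_rejection: str = "blank_interpolate"  # or "off"
    crop_above_target: bool = False
    slew_mad_factor: float = 8.0   # threshold = factor x MAD(|diff|)
    blank_ms: float = 20.0         # half-width of the blanked span

    def __post_init__(self) -> None:
        if abs(self.pre_trigger_s + self.post_trigger_s - self.target_s) > 1e-9:
            raise ParameterError(
                "pre_trigger_s + post_trigger_s must equal target_s"
            )
        if not (self.short_threshold_s < self.target_s <= self.long_threshold_s):
            raise ParameterError(
                "thresholds must satisfy short_threshold_s < target_s "
                "<= long_threshold_s"
            )
        if self.artifact_rejection not in ("off", "blank_interpolate"):
            raise ParameterError(
                f"unknown artifact_rejection mode {self.artifact_rejection!r}"
            )


def normalize_length(
    record: IEEGRecord, cfg: PreprocessConfig | None = None
) -> IEEGRecord:
    """Bring a record to the target length.

    Short records (< ``short_threshold_s``) are extended to ``target_s``
    by prepending the first ``target_s - L`` seconds of the record; long
    records (> ``long_threshold_s``, or > ``target_s`` when
    ``crop_above_target`` is set) are cropped to
    ``[trigger - pre_trigger_s, trigger + post_trigger_s)``, with any
    deficit at a record boundary taken from the other side. All present
    channels are cut identically and the trigger offset is updated to
    stay aligned with the same instant of brain activity.
    """
    cfg = cfg or PreprocessConfig()
    if not record.present_channels:
        raise DataError(f"record {record.record_id} has no present channels")

    dur = record.duration_s
    target_n = n_samples(cfg.target_s)
    crop_threshold = cfg.target_s if cfg.crop_above_target else cfg.long_threshold_s

    if dur < cfg.short_threshold_s:
        pad_n = target_n - record.n_samples
        if pad_n > record.n_samples:
            # record shorter than half the target: tile from the start
            reps = int(np.ceil(pad_n / record.n_samples))
        else:
            reps = 1
        new_channels = []
        for ch in record.channels:
            if ch is None:
                new_channels.append(None)
                continue
            if ch.size == 0:
                raise DataError(
                    f"record {record.record_id}: zero-length channel"
                )
            pad = np.tile(ch, reps)[:pad_n]
            new_channels.append(np.concatenate([pad, ch]))
        return record.with_channels(
            new_channels,
            duration_s=cfg.target_s,
            trigger_offset_s=record.trigger_offset_s + pad_n / FS,
        )

    if dur > crop_threshold:
        trigger = record.trigger_offset_s
        if not np.isfinite(trigger):
            warnings.warn(
                f"record {record.record_id}: no trigger time; cropping "
                "around the record midpoint"
            )
            trigger = dur / 2.0
        start = trigger - cfg.pre_trigger_s
        # clamp to bounds, taking the deficit from the other side
        if start < 0.0:
            start = 0.0
        if start + cfg.target_s > dur:
            start = dur - cfg.target_s
        a = n_samples(start)
        b = a + target_n
        new_channels = [
            None if ch is None else ch[a:b] for ch in record.channels
        ]
        return record.with_channels(
            new_channels,
            duration_s=cfg.target_s,
            trigger_offset_s=trigger - a / FS,
        )

    return record


def reject_stim_artifacts(
    record: IEEGRecord, cfg: PreprocessConfig | None = None
) -> tuple[IEEGRecord, np.ndarray]:
    """Blank high-slew stimulation pulses and interpolate across them.

    Returns the cleaned record and a boolean mask of shape
    ``(4, n_samples)`` marking replaced samples (all-false rows for
    absent channels). Per channel, samples where the absolute first
    difference exceeds ``slew_mad_factor`` times the median absolute
    deviation of the differenced signal are blanked with a ±``blank_ms``
    guard and bridged by linear interpolation. A record with no
    detections is returned unchanged.
    """
    cfg = cfg or PreprocessConfig()
    n = record.n_samples
    mask = np.zeros((len(record.channels), n), dtype=bool)
    if cfg.artifact_rejection == "off":
        return record, mask

    guard = max(1, n_samples(cfg.blank_ms / 1000.0))
    new_channels: list[np.ndarray | None] = []
    any_hit = False
    for i, ch in enumerate(record.channels):
        if ch is None:
            new_channels.append(None)
            continue
        d = np.abs(np.diff(ch))
        mad = np.median(np.abs(d - np.median(d)))
        if mad <= 0:
            mad = d.std() + 1e-12
        hits = np.flatnonzero(d > cfg.slew_mad_factor * mad * 1.4826)
        if hits.size == 0:
            new_channels.append(ch)
            continue
        any_hit = True
        m = np.zeros(n, dtype=bool)
        for h in hits:
            m[max(0, h - guard) : min(n, h + 1 + guard)] = True
        mask[i] = m
        cleaned = ch.copy()
        idx = np.arange(n)
        keep = ~m
        if keep.sum() >= 2:
            cleaned[m] = np.interp(idx[m], idx[keep], ch[keep])
        else:
            warnings.warn(
                f"record {record.record_id} channel {i + 1}: nearly all "
                "samples flagged as artifact; leaving channel unchanged"
            )
            cleaned, mask[i] = ch, False
        new_channels.append(cleaned)

    if not any_hit:
        return record, mask
    return record.with_channels(new_channels), mask


def preprocess_record(
    record: IEEGRecord, cfg: PreprocessConfig | None = None
) -> IEEGRecord:
    """Full preprocessing: length normalization then artifact rejection."""
    cfg = cfg or PreprocessConfig()
    out = normalize_length(record, cfg)
    out, _ = reject_stim_artifacts(out, cfg)
    return out
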