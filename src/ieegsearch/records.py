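"""Core iEEG record container.

An iEEG record is one stored event: up to four channels of samples at
250 Hz plus storage-trigger metadata. Channels are differentially recorded
between adjacent electrode contacts; a channel a device did not record is
represented explicitly as ``None`` (absent), never zero-filled at this
layer — zero substitution happens only when features are combined.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .errors import DataError

#: Device sampling rate in samples per second.
FS = 250

#: Number of channel slots in every record.
N_CHANNELS = 4


class TriggerType(str, Enum):
    """Why the device stored the record."""

    LONG_EPISODE = "long_episode"  # long train of detected abnormal activity
    SCHEDULED = "scheduled"        # time-of-day storage, typically baseline
    MAGNET = "magnet"              # patient/caregiver magnet swipe
    SATURATION = "saturation"      # amplifier saturation


def n_samples(duration_s: float) -> int:
    """Number of samples for a duration at the device rate."""
    return int(round(duration_s * FS))


@dataclass
class IEEGRecord:
    """One stored iEEG event.

    Parameters
    ----------
    patient_id, record_id
        Identifiers; ``record_id`` is unique within a patient.
    channels
        Length-4 list of sample arrays (float, microvolts) or ``None``
        for channels the device did not record.
    duration_s
        Record duration in seconds. Every present channel must hold
        exactly ``round(duration_s * 250)`` samples.
    trigger_offset_s
        Storage-trigger time measured from record start, in seconds.
    trigger_type
        Storage trigger class.
    ground_truth_template
        For synthetic records: the morphology template that generated the
        record. ``None`` for real data.
    """

    patient_id: str
    record_id: str
    channels: list[np.ndarray | None]
    duration_s: float
    trigger_offset_s: float
    trigger_type: TriggerType = TriggerType.SCHEDULED
    ground_truth_template: str | None = field(default=None)

    def __post_init__(self) -> None:
        if len(self.channels) != N_CHANNELS:
            raise DataError(
                f"record {self.record_id}: expected {N_CHANNELS} channel "
                f"slots, got {len(self.channels)}"
            )
        self.trigger_type = TriggerType(self.trigger_type)
        expected = n_samples(self.duration_s)
        for i, ch in enumerate(self.channels):
            if ch is None:
                continue
            ch = np.asarray(ch, dtype=np.float64)
            self.channels[i] = ch
            if ch.ndim != 1 or ch.size != expected:
                raise DataError(
                    f"record {self.record_id} channel {i + 1}: expected "
                    f"{expected} samples for {self.duration_s} s, got {ch.size}"
                )
        # NaN marks an unknown trigger time (e.g. bare EDF imports)
        if not np.isnan(self.trigger_offset_s) and not (
            0.0 <= self.trigger_offset_s <= self.duration_s
        ):
            raise DataError(
                f"record {self.record_id}: trigger_offset_s "
                f"{self.trigger_offset_s} outside [0, {self.duration_s}]"
            )

    @property
    def present_channels(self) -> list[int]:
        """Zero-based indices of channels that hold samples."""
        return [i for i, ch in enumerate(self.channels) if ch is not None]

    @property
    def missing_channels(self) -> list[int]:
        """Zero-based indices of absent channels."""
        return [i for i, ch in enumerate(self.channels) if ch is None]

    @property
    def n_samples(self) -> int:
        return n_samples(self.duration_s)

    def with_channels(self, channels, duration_s=None, trigger_offset_s=None):
        """Copy of the record with replaced samples (and optional timing)."""
        return replace(
            self,
            channels=list(channels),
            duration_s=self.duration_s if duration_s is None else duration_s,
            trigger_offset_s=(
                self.trigger_offset_s
                if trigger_offset_s is None
                else trigger_offset_s
            ),
        )
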