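"""Synthetic iEEG patients with stereotyped within-patient morphologies.

Chronic neurostimulator recordings have a property the whole pipeline
leans on: within one patient the stored events fall into a small number of
stereotyped electrographic morphologies, while morphologies differ across
patients. This module generates seeded patients with exactly that
structure — each patient owns a handful of morphology templates
(baseline, interictal spiking, high-frequency-band seizures, harmonic
seizures, stimulation artifact, amplifier saturation) and every generated
record carries its ground-truth template label, so clustering and
retrieval stages can be property-tested without any real data.

The background is pink (1/f) noise plus white sensor noise, which gives
synthetic spectrograms the qualitative low-frequency-dominant look of real
iEEG; no attempt is made at biophysically realistic seizure dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import DataError, FormatError, ParameterError
from .records import FS, N_CHANNELS, IEEGRecord, TriggerType, n_samples

NYQUIST_HZ = FS / 2.0


class EventClass(str, Enum):
    BASELINE = "baseline"
    INTERICTAL_SPIKE = "interictal_spike"
    SEIZURE_HF_BAND = "seizure_hf_band"
    SEIZURE_HARMONICS = "seizure_harmonics"
    STIM_ARTIFACT = "stim_artifact"
    SATURATION = "saturation"


#: Storage trigger implied by each event class: seizure-bearing records are
#: long-episode triggered, baseline/spiking records are scheduled.
_TRIGGER_FOR_CLASS = {
    EventClass.BASELINE: TriggerType.SCHEDULED,
    EventClass.INTERICTAL_SPIKE: TriggerType.SCHEDULED,
    EventClass.SEIZURE_HF_BAND: TriggerType.LONG_EPISODE,
    EventClass.SEIZURE_HARMONICS: TriggerType.LONG_EPISODE,
    EventClass.STIM_ARTIFACT: TriggerType.MAGNET,
    EventClass.SATURATION: TriggerType.SATURATION,
}

#: Trigger offset from record start (s). Long episodes trigger 30 s in, so
#: the crop rule [trigger-30, trigger+60) is exercised; scheduled records
#: trigger at the start.
_TRIGGER_OFFSET_FOR = {
    TriggerType.LONG_EPISODE: 30.0,
    TriggerType.SCHEDULED: 0.0,
    TriggerType.MAGNET: 0.0,
    TriggerType.SATURATION: 30.0,
}

_DEFAULT_PARAMS: dict[EventClass, dict] = {
    EventClass.BASELINE: {},
    EventClass.INTERICTAL_SPIKE: {
        "spike_rate_per_min": 20.0,     # events/min
        "spike_amplitude_uv": 300.0,
        "spike_width_s": 0.06,
    },
    EventClass.SEIZURE_HF_BAND: {
        "band_hz": (50.0, 75.0),        # ictal high-frequency band edges
        "ictal_duration_s": 35.0,
        "ictal_amplitude_uv": 150.0,
    },
    EventClass.SEIZURE_HARMONICS: {
        "f0_hz": 10.0,                  # fundamental
        "n_harmonics": 3,               # components above the fundamental
        "ictal_duration_s": 30.0,
        "ictal_amplitude_uv": 150.0,
    },
    EventClass.STIM_ARTIFACT: {
        "pulse_period_s": 5.0,
        "pulse_width_s": 0.1,
        "pulse_amplitude_uv": 1000.0,
    },
    EventClass.SATURATION: {
        "saturation_limit_uv": 400.0,
        "drive_amplitude_uv": 1500.0,
    },
}


@dataclass
class MorphologyTemplate:
    """One stereotyped activity pattern of one synthetic patient.

    ``params`` are event-class specific (spike rate in events/min, chirp
    band edges in Hz, harmonic count, ictal duration in s, ...) on top of
    the shared keys ``amplitude_uv`` (background scale, microvolts) and
    ``involved_channels`` (length-4 boolean mask of channels expressing
    the event; uninvolved channels carry background only).
    """

    template_id: str
    event_class: EventClass
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.event_class = EventClass(self.event_class)
        merged = dict(_DEFAULT_PARAMS[self.event_class])
        merged.setdefault("amplitude_uv", 40.0)
        merged.setdefault("involved_channels", (True,) * N_CHANNELS)
        merged.update(self.params)
        self.params = merged
        mask = self.params["involved_channels"]
        if len(mask) != N_CHANNELS:
            raise ParameterError(
                f"template {self.template_id}: involvement mask must have "
                f"length {N_CHANNELS}, got {len(mask)}"
            )
        if "band_hz" in self.params:
            lo, hi = self.params["band_hz"]
            if not (0.0 <= lo < hi <= NYQUIST_HZ):
                raise ParameterError(
                    f"template {self.template_id}: band edges ({lo}, {hi}) Hz "
                    f"must lie within [0, {NYQUIST_HZ}] Hz"
                )
        if "f0_hz" in self.params:
            f0 = self.params["f0_hz"]
            top = f0 * (1 + int(self.params.get("n_harmonics", 0)))
            if not (0.0 < f0 and top <= NYQUIST_HZ):
                raise ParameterError(
                    f"template {self.template_id}: harmonic stack reaches "
                    f"{top} Hz, beyond the {NYQUIST_HZ} Hz Nyquist limit"
                )


@dataclass
class SynthPatientSpec:
    """Recipe for one synthetic patient."""

    patient_id: str
    templates: list[MorphologyTemplate]
    records_per_template: int = 10
    record_duration_s: float = 90.0
    missing_channels: frozenset[int] = frozenset()  # 1-based channel numbers
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.templates:
            raise ParameterError(f"patient {self.patient_id}: needs >=1 template")
        if self.records_per_template < 1:
            raise ParameterError("records_per_template must be >= 1")
        if not (30.0 <= self.record_duration_s <= 240.0):
            raise ParameterError(
                f"record_duration_s {self.record_duration_s} outside the "
                "supported 30-240 s range"
            )
        self.missing_channels = frozenset(self.missing_channels)
        if any(c < 1 or c > N_CHANNELS for c in self.missing_channels):
            raise ParameterError("missing_channels entries must be in 1..4")


# ---------------------------------------------------------------------------
# waveform synthesis


def _background(rng: np.random.Generator, n: int, amplitude_uv: float) -> np.ndarray:
    """Pink (1/f) noise plus 20% white sensor noise, scaled to an RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / FS)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    shaping[0] = 0.0
    pink = np.fft.irfft(spec * shaping, n=n)
    pink /= max(pink.std(), 1e-12)
    sensor = rng.standard_normal(n)
    x = 0.8 * pink + 0.2 * sensor
    return amplitude_uv * x


def _tukey_window(n: int, alpha: float = 0.25) -> np.ndarray:
    from scipy.signal import windows

    return windows.tukey(n, alpha=alpha)


def _ictal_span(duration_s: float, params: dict) -> tuple[int, int]:
    """Sample span of the ictal event, centred on the default trigger."""
    ictal = min(float(params["ictal_duration_s"]), duration_s)
    onset = params.get("onset_s")
    if onset is None:
        onset = max(0.0, min(duration_s - ictal, duration_s / 2.0 - ictal / 2.0))
    start = n_samples(onset)
    stop = min(start + n_samples(ictal), n_samples(duration_s))
    return start, stop


def make_event_waveform(
    event_class: EventClass | str,
    params: dict | None,
    duration_s: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Synthesize one channel of one event.

    Returns ``round(duration_s * 250)`` samples in microvolts. Baseline is
    band-limited (pink + white) noise; interictal spiking adds sparse
    biphasic transients; the seizure classes add a Tukey-windowed chirp —
    either a high-frequency band sweep or a harmonic stack; stimulation
    artifact adds periodic high-slew biphasic square pulses; saturation
    drives the signal into symmetric clipping rails.
    """
    try:
        event_class = EventClass(event_class)
    except ValueError:
        raise ParameterError(f"unknown event class: {event_class!r}") from None
    merged = dict(_DEFAULT_PARAMS[event_class])
    merged.setdefault("amplitude_uv", 40.0)
    if params:
        merged.update(params)
    params = merged

    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = n_samples(duration_s)
    t = np.arange(n) / FS
    x = _background(rng, n, float(params["amplitude_uv"]))

    if event_class is EventClass.BASELINE:
        return x

    if event_class is EventClass.INTERICTAL_SPIKE:
        rate = float(params["spike_rate_per_min"])
        count = int(round(rate * duration_s / 60.0))
        width = float(params["spike_width_s"])
        amp = float(params["spike_amplitude_uv"])
        # jittered but collision-free spike times across the record
        slots = np.linspace(0.05, 0.95, max(count, 1)) * duration_s
        jitter = rng.uniform(-0.3, 0.3, size=slots.shape) * duration_s / max(count, 1)
        times = np.clip(slots + jitter, width, duration_s - width)[:count]
        sigma = width / 4.0
        for t0 in times:
            lo = max(0, n_samples(t0 - 3 * sigma))
            hi = min(n, n_samples(t0 + 3 * sigma))
            tt = t[lo:hi] - t0
            # biphasic transient: derivative of a Gaussian
            x[lo:hi] += amp * (-tt / sigma) * np.exp(0.5 - tt**2 / (2 * sigma**2))
        return x

    if event_class is EventClass.SEIZURE_HF_BAND:
        lo_hz, hi_hz = params["band_hz"]
        if not (0.0 <= lo_hz < hi_hz <= NYQUIST_HZ):
            raise ParameterError(
                f"band edges ({lo_hz}, {hi_hz}) Hz outside [0, {NYQUIST_HZ}]"
            )
        start, stop = _ictal_span(duration_s, params)
        tt = t[start:stop] - t[start]
        span = max(tt[-1], 1e-9) if tt.size else 1.0
        # sweep up through the band and ripple back: onset-offset structure
        inst_freq = lo_hz + (hi_hz - lo_hz) * 0.5 * (1 - np.cos(2 * np.pi * tt / span))
        phase = 2 * np.pi * np.cumsum(inst_freq) / FS
        burst = np.sin(phase + rng.uniform(0, 2 * np.pi))
        x[start:stop] += (
            float(params["ictal_amplitude_uv"]) * _tukey_window(stop - start) * burst
        )
        return x

    if event_class is EventClass.SEIZURE_HARMONICS:
        f0 = float(params["f0_hz"])
        n_h = int(params["n_harmonics"])
        start, stop = _ictal_span(duration_s, params)
        tt = t[start:stop] - t[start]
        stack = np.zeros_like(tt)
        phase0 = rng.uniform(0, 2 * np.pi)
        for k in range(1, n_h + 2):  # fundamental + n_harmonics overtones
            stack += np.sin(2 * np.pi * k * f0 * tt + k * phase0) / k
        x[start:stop] += (
            float(params["ictal_amplitude_uv"]) * _tukey_window(stop - start) * stack
        )
        return x

    if event_class is EventClass.STIM_ARTIFACT:
        period = float(params["pulse_period_s"])
        width = float(params["pulse_width_s"])
        amp = float(params["pulse_amplitude_uv"])
        count = int(np.floor(duration_s / period))
        for k in range(count):
            t0 = (k + 0.5) * period
            a = n_samples(t0)
            b = min(n, a + n_samples(width))
            half = (a + b) // 2
            x[a:half] += amp          # instantaneous rail-to-rail transition
            x[half:b] -= amp
        return x

    if event_class is EventClass.SATURATION:
        limit = float(params["saturation_limit_uv"])
        drive = float(params["drive_amplitude_uv"])
        x = x + drive * np.sin(2 * np.pi * 2.0 * t + rng.uniform(0, 2 * np.pi))
        return np.clip(x, -limit, limit)

    raise ParameterError(f"unknown event class: {event_class!r}")


def make_patient(spec: SynthPatientSpec) -> list[IEEGRecord]:
    """Generate all records of one synthetic patient.

    Produces ``records_per_template x len(templates)`` records, each
    labelled with its generating template. Identical spec + seed gives
    bit-identical samples: every record/channel draws from its own
    ``SeedSequence`` spawned from (seed, template index, record index,
    channel index).
    """
    records: list[IEEGRecord] = []
    missing0 = {c - 1 for c in spec.missing_channels}
    rec_no = 0
    for ti, tpl in enumerate(spec.templates):
        mask = tpl.params["involved_channels"]
        for ri in range(spec.records_per_template):
            channels: list[np.ndarray | None] = []
            for ci in range(N_CHANNELS):
                if ci in missing0:
                    channels.append(None)
                    continue
                rng = np.random.default_rng(
                    np.random.SeedSequence([spec.seed, ti, ri, ci])
                )
                cls = tpl.event_class if mask[ci] else EventClass.BASELINE
                prm = (
                    tpl.params
                    if mask[ci]
                    else {"amplitude_uv": tpl.params["amplitude_uv"]}
                )
                channels.append(
                    make_event_waveform(cls, prm, spec.record_duration_s, rng)
                )
            trig = _TRIGGER_FOR_CLASS[tpl.event_class]
            offset = min(_TRIGGER_OFFSET_FOR[trig], spec.record_duration_s)
            records.append(
                IEEGRecord(
                    patient_id=spec.patient_id,
                    record_id=f"{spec.patient_id}-r{rec_no:05d}",
                    channels=channels,
                    duration_s=spec.record_duration_s,
                    trigger_offset_s=offset,
                    trigger_type=trig,
                    ground_truth_template=tpl.template_id,
                )
            )
            rec_no += 1
    return records


# ---------------------------------------------------------------------------
# fixture container (one HDF5 file per patient)

_REQUIRED_ATTRS = (
    "patient_id",
    "record_id",
    "duration_s",
    "trigger_offset_s",
    "trigger_type",
)


def write_fixture(records: list[IEEGRecord], path) -> None:
    """Write records to a per-patient HDF5 container.

    Layout: one group per record holding datasets ``ch1..ch4`` (absent
    channels simply have no dataset) and the metadata as group attributes.
    """
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["format"] = "ieegsearch-fixture-v1"
        for rec in records:
            g = f.create_group(rec.record_id)
            g.attrs["patient_id"] = rec.patient_id
            g.attrs["record_id"] = rec.record_id
            g.attrs["duration_s"] = rec.duration_s
            g.attrs["trigger_offset_s"] = rec.trigger_offset_s
            g.attrs["trigger_type"] = rec.trigger_type.value
            if rec.ground_truth_template is not None:
                g.attrs["template_id"] = rec.ground_truth_template
            for i, ch in enumerate(rec.channels):
                if ch is not None:
                    g.create_dataset(f"ch{i + 1}", data=ch)


def read_fixture(path) -> list[IEEGRecord]:
    """Read a fixture container back; lossless inverse of ``write_fixture``."""
    import h5py

    records = []
    with h5py.File(path, "r") as f:
        for rid in sorted(f.keys()):
            g = f[rid]
            for name in _REQUIRED_ATTRS:
                if name not in g.attrs:
                    raise FormatError(
                        f"record group {rid!r} is missing field {name!r}",
                        field=name,
                    )
            channels = [
                np.asarray(g[f"ch{i + 1}"]) if f"ch{i + 1}" in g else None
                for i in range(N_CHANNELS)
            ]
            if all(ch is None for ch in channels):
                raise FormatError(
                    f"record group {rid!r} has no channel data", field="channels"
                )
            records.append(
                IEEGRecord(
                    patient_id=str(g.attrs["patient_id"]),
                    record_id=str(g.attrs["record_id"]),
                    channels=channels,
                    duration_s=float(g.attrs["duration_s"]),
                    trigger_offset_s=float(g.attrs["trigger_offset_s"]),
                    trigger_type=TriggerType(str(g.attrs["trigger_type"])),
                    ground_truth_template=(
                        str(g.attrs["template_id"]) if "template_id" in g.attrs else None
                    ),
                )
            )
    return records


def write_edf(record: IEEGRecord, path) -> None:
    """Export one record's present channels to EDF (see :mod:`._edf`)."""
    from ._edf import write_edf as _write

    _write(record, path)


def read_edf(path) -> IEEGRecord:
    """Import an EDF file written by :func:`write_edf`."""
    from ._edf import read_edf as _read

    return _read(path)


# ---------------------------------------------------------------------------
# ready-made patient recipes used by tests, demos and the CLI


def example_templates(style: int, rng: np.random.Generator | None = None) -> list[MorphologyTemplate]:
    """A small library of well-separated template sets.

    ``style`` indexes deterministic variations so that different synthetic
    patients get distinct morphologies (different chirp bands, spike
    rates, fundamentals).
    """
    band_lo = 50.0 + 5.0 * (style % 5)
    f0 = 6.0 + 2.0 * (style % 4)
    rate = 8.0 * (1 + style % 3)
    return [
        MorphologyTemplate(f"s{style}-base", EventClass.BASELINE),
        MorphologyTemplate(
            f"s{style}-spike",
            EventClass.INTERICTAL_SPIKE,
            {"spike_rate_per_min": rate},
        ),
        MorphologyTemplate(
            f"s{style}-hfb",
            EventClass.SEIZURE_HF_BAND,
            {"band_hz": (band_lo, band_lo + 20.0)},
        ),
        MorphologyTemplate(
            f"s{style}-harm",
            EventClass.SEIZURE_HARMONICS,
            {"f0_hz": f0, "n_harmonics": 3},
        ),
    ]
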