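"""Minimal EDF (European Data Format) export/import.

Implements the plain EDF layout: a 256-byte fixed header, 256 bytes of
header per signal, then contiguous 1-second data records of little-endian
16-bit integers. Only what the package needs for interoperability is
covered — continuous recordings with integer-second durations and a
shared sampling rate. Annotations, EDF+ and discontinuous files are out
of scope; for reading such files use a full EDF library.
"""

from __future__ import annotations

import numpy as np

from .errors import DataError, FormatError
from .records import FS, N_CHANNELS, IEEGRecord, TriggerType


def _field(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        raise FormatError(f"EDF header field too long: {value!r} > {width}")
    return b.ljust(width)


def write_edf(record: IEEGRecord, path) -> None:
    """Write a record's present channels as 16-bit EDF.

    Samples are linearly quantized per channel between that channel's
    physical min/max over the full digital range, the usual EDF scaling.
    """
    if abs(record.duration_s - round(record.duration_s)) > 1e-9:
        raise DataError(
            "EDF export requires an integer number of seconds; "
            f"got {record.duration_s}"
        )
    n_rec = int(round(record.duration_s))
    chans = record.present_channels
    if not chans:
        raise DataError("record has no present channels to export")
    ns = len(chans)

    header = b"".join(
        [
            _field("0", 8),
            _field(record.patient_id, 80),
            _field(f"record {record.record_id}", 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(str(256 * (1 + ns)), 8),
            _field(f"trigger={record.trigger_type.value}@{record.trigger_offset_s:g}", 44),
            _field(str(n_rec), 8),
            _field("1", 8),
            _field(str(ns), 4),
        ]
    )

    phys_min, phys_max, scaled = [], [], []
    for ci in chans:
        x = record.channels[ci]
        lo = float(np.floor(min(x.min(), -1.0)))
        hi = float(np.ceil(max(x.max(), 1.0)))
        phys_min.append(lo)
        phys_max.append(hi)
        dig = np.round((x - lo) / (hi - lo) * 65535.0 - 32768.0)
        scaled.append(dig.astype("<i2"))

    def sig_fields(values: list[str], width: int) -> bytes:
        return b"".join(_field(v, width) for v in values)

    header += sig_fields([f"iEEG ch{ci + 1}" for ci in chans], 16)
    header += sig_fields([""] * ns, 80)                       # transducer
    header += sig_fields(["uV"] * ns, 8)                      # physical dim
    header += sig_fields([f"{v:g}" for v in phys_min], 8)
    header += sig_fields([f"{v:g}" for v in phys_max], 8)
    header += sig_fields(["-32768"] * ns, 8)
    header += sig_fields(["32767"] * ns, 8)
    header += sig_fields([""] * ns, 80)                       # prefiltering
    header += sig_fields([str(FS)] * ns, 8)                   # samples/record
    header += sig_fields([""] * ns, 32)                       # reserved

    with open(path, "wb") as f:
        f.write(header)
        for r in range(n_rec):
            for dig in scaled:
                f.write(dig[r * FS : (r + 1) * FS].tobytes())


def _read_fields(buf: bytes, pos: int, ns: int, width: int):
    out = []
    for _ in range(ns):
        out.append(buf[pos : pos + width].decode("ascii").strip())
        pos += width
    return out, pos


def read_edf(path) -> IEEGRecord:
    """Read an EDF file (as written by :func:`write_edf`) into a record.

    Channel slots are filled by the ``ch<N>`` suffix of each signal
    label when present, so a record exported with a missing channel round
    trips with the gap preserved.
    """
    with open(path, "rb") as f:
        buf = f.read()
    if len(buf) < 256:
        raise FormatError("file too short for an EDF header", field="header")
    patient = buf[8:88].decode("ascii", "replace").strip()
    try:
        n_rec = int(buf[236:244])
        rec_dur = float(buf[244:252])
        ns = int(buf[252:256])
    except ValueError as e:
        raise FormatError(f"malformed EDF header counts: {e}", field="header")
    pos = 256
    labels, pos = _read_fields(buf, pos, ns, 16)
    _, pos = _read_fields(buf, pos, ns, 80)
    _, pos = _read_fields(buf, pos, ns, 8)
    pmin, pos = _read_fields(buf, pos, ns, 8)
    pmax, pos = _read_fields(buf, pos, ns, 8)
    dmin, pos = _read_fields(buf, pos, ns, 8)
    dmax, pos = _read_fields(buf, pos, ns, 8)
    _, pos = _read_fields(buf, pos, ns, 80)
    spr, pos = _read_fields(buf, pos, ns, 8)
    _, pos = _read_fields(buf, pos, ns, 32)
    spr = [int(v) for v in spr]

    data = np.frombuffer(buf[pos:], dtype="<i2")
    per_rec = sum(spr)
    if data.size < n_rec * per_rec:
        raise FormatError("EDF data section shorter than declared", field="data")

    sigs = [np.empty(n_rec * s, dtype=np.float64) for s in spr]
    cursor = 0
    for r in range(n_rec):
        for i, s in enumerate(spr):
            sigs[i][r * s : (r + 1) * s] = data[cursor : cursor + s]
            cursor += s
    for i in range(ns):
        lo, hi = float(pmin[i]), float(pmax[i])
        dlo, dhi = float(dmin[i]), float(dmax[i])
        sigs[i] = (sigs[i] - dlo) / (dhi - dlo) * (hi - lo) + lo

    channels: list[np.ndarray | None] = [None] * N_CHANNELS
    for i, label in enumerate(labels):
        slot = None
        if label and label[-1].isdigit():
            cand = int(label[-1]) - 1
            if 0 <= cand < N_CHANNELS and channels[cand] is None:
                slot = cand
        if slot is None:
            slot = next(j for j in range(N_CHANNELS) if channels[j] is None)
        channels[slot] = sigs[i]

    trig_type, trig_off = TriggerType.SCHEDULED, 0.0
    reserved = buf[192:236].decode("ascii", "replace").strip()
    if reserved.startswith("trigger="):
        try:
            name, off = reserved[len("trigger=") :].split("@")
            trig_type, trig_off = TriggerType(name), float(off)
        except ValueError:
            pass
    return IEEGRecord(
        patient_id=patient or "unknown",
        record_id="edf-import",
        channels=channels,
        duration_s=n_rec * rec_dur,
        trigger_offset_s=trig_off,
        trigger_type=trig_type,
    )
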