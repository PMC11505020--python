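"""Minimal EDF (European Data Format) reader/writer.

Implements the classic 16-bit EDF layout: a 256-byte fixed ASCII header,
256 bytes of per-signal header fields, and little-endian int16 data
records.  Physical values are mapped linearly onto the digital range
[-32768, 32767] per channel, so a write/read round trip is exact up to
one quantization step of the per-channel physical range.

Only equal-sampling-rate, continuous recordings are supported, which is
all the package needs; anything fancier should go through a dedicated
EDF library.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass

import numpy as np

HEADER_BYTES = 256
SIGNAL_HEADER_BYTES = 256
DIG_MIN = -32768
DIG_MAX = 32767


class EDFFormatError(ValueError):
    """Raised when a file does not parse as valid EDF."""


@dataclass
class EDFRecording:
    """Continuous multichannel signal read from / destined for an EDF file."""

    signals: np.ndarray  # (n_channels, n_samples), physical units
    fs: float
    channel_names: list[str]
    physical_dimension: str = "uV"


def _field(text: str, width: int) -> bytes:
    raw = text.encode("ascii", errors="replace")[:width]
    return raw.ljust(width, b" ")


def _num_field(value, width: int) -> bytes:
    text = f"{value:.10g}"[:width]
    return _field(text, width)


def write_edf(path, rec: EDFRecording) -> None:
    """Write a continuous recording as 16-bit EDF.

    One data record per second when the sampling rate is integral,
    otherwise a single record spanning the whole signal.  Trailing
    samples that do not fill a record are dropped (EDF records are
    fixed-size).
    """
    sig = np.asarray(rec.signals, dtype=float)
    if sig.ndim != 2:
        raise ValueError("signals must be 2-D (channels x samples)")
    n_ch, n_samp = sig.shape
    if n_ch == 0 or n_samp == 0:
        raise ValueError("cannot write an empty recording")

    fs = float(rec.fs)
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    if abs(fs - round(fs)) < 1e-9:
        samples_per_record = int(round(fs))
        record_duration = 1.0
    else:
        samples_per_record = n_samp
        record_duration = n_samp / fs
    n_records = n_samp // samples_per_record
    if n_records == 0:
        samples_per_record = n_samp
        record_duration = n_samp / fs
        n_records = 1
    used = n_records * samples_per_record

    # per-channel physical range; degenerate (constant) channels get a
    # +/-1 span so the scaling stays invertible
    phys_min = sig[:, :used].min(axis=1)
    phys_max = sig[:, :used].max(axis=1)
    flat = phys_max - phys_min < 1e-12
    phys_min[flat] -= 1.0
    phys_max[flat] += 1.0

    scale = (DIG_MAX - DIG_MIN) / (phys_max - phys_min)
    digital = np.rint(
        (sig[:, :used] - phys_min[:, None]) * scale[:, None] + DIG_MIN
    ).astype(np.int16)

    now = datetime.datetime(2000, 1, 1)
    header_len = HEADER_BYTES + n_ch * SIGNAL_HEADER_BYTES
    parts = [
        _field("0", 8),
        _field("X X X X", 80),
        _field("Startdate X X X X", 80),
        _field(now.strftime("%d.%m.%y"), 8),
        _field(now.strftime("%H.%M.%S"), 8),
        _num_field(header_len, 8),
        _field("", 44),
        _num_field(n_records, 8),
        _num_field(record_duration, 8),
        _num_field(n_ch, 4),
    ]
    names = list(rec.channel_names)
    if len(names) != n_ch:
        raise ValueError("channel_names length does not match signals")
    for column, width in (
        (names, 16),
        (["" for _ in names], 80),
        ([rec.physical_dimension for _ in names], 8),
        ([f"{v:.6g}" for v in phys_min], 8),
        ([f"{v:.6g}" for v in phys_max], 8),
        ([str(DIG_MIN) for _ in names], 8),
        ([str(DIG_MAX) for _ in names], 8),
        (["" for _ in names], 80),
        ([str(samples_per_record) for _ in names], 8),
        (["" for _ in names], 32),
    ):
        for item in column:
            parts.append(_field(str(item), width))

    # EDF stores each record channel-by-channel
    blocks = digital.reshape(n_ch, n_records, samples_per_record)
    body = blocks.transpose(1, 0, 2).tobytes()
    with open(path, "wb") as fh:
        fh.write(b"".join(parts))
        fh.write(body)


def _parse_float(raw: bytes, offset: int, what: str) -> float:
    try:
        return float(raw.decode("ascii").strip())
    except ValueError as exc:
        raise EDFFormatError(
            f"unparseable {what} field at byte offset {offset}"
        ) from exc


def read_edf_recording(path) -> EDFRecording:
    """Read a 16-bit EDF file into physical units."""
    with open(path, "rb") as fh:
        head = fh.read(HEADER_BYTES)
        if len(head) < HEADER_BYTES:
            raise EDFFormatError(
                f"truncated EDF header: file ends at byte {len(head)}"
            )
        n_records = int(_parse_float(head[236:244], 236, "record count"))
        record_duration = _parse_float(head[244:252], 244, "record duration")
        n_ch = int(_parse_float(head[252:256], 252, "signal count"))
        if n_ch <= 0:
            raise EDFFormatError("EDF file declares zero signals")

        sig_head = fh.read(n_ch * SIGNAL_HEADER_BYTES)
        if len(sig_head) < n_ch * SIGNAL_HEADER_BYTES:
            raise EDFFormatError(
                "truncated EDF signal header: file ends at byte "
                f"{HEADER_BYTES + len(sig_head)}"
            )

        # field offsets within the signal header block, in bytes per signal:
        # label 16 | transducer 80 | dim 8 | pmin 8 | pmax 8 | dmin 8 |
        # dmax 8 | prefilter 80 | samples 8 | reserved 32
        offsets = [0, 16, 96, 104, 112, 120, 128, 136, 216, 224]
        widths = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]

        def fields(idx: int) -> list[bytes]:
            start = n_ch * offsets[idx]
            w = widths[idx]
            return [
                sig_head[start + i * w : start + (i + 1) * w]
                for i in range(n_ch)
            ]

        names = [b.decode("ascii").strip() for b in fields(0)]
        phys_dim = fields(2)[0].decode("ascii").strip() or "uV"
        pmin = np.array(
            [_parse_float(b, 0, "physical minimum") for b in fields(3)]
        )
        pmax = np.array(
            [_parse_float(b, 0, "physical maximum") for b in fields(4)]
        )
        dmin = np.array(
            [_parse_float(b, 0, "digital minimum") for b in fields(5)]
        )
        dmax = np.array(
            [_parse_float(b, 0, "digital maximum") for b in fields(6)]
        )
        spr = np.array(
            [int(_parse_float(b, 0, "samples per record")) for b in fields(8)]
        )
        if len(set(spr.tolist())) != 1:
            raise EDFFormatError(
                "mixed per-signal sampling rates are not supported"
            )
        samples_per_record = int(spr[0])
        if record_duration <= 0:
            raise EDFFormatError("non-positive record duration")
        fs = samples_per_record / record_duration

        expected = 2 * n_records * n_ch * samples_per_record
        body = fh.read()
        if len(body) < expected:
            raise EDFFormatError(
                "truncated EDF data section: file ends at byte "
                f"{HEADER_BYTES + n_ch * SIGNAL_HEADER_BYTES + len(body)}, "
                f"expected {expected} data bytes"
            )
        digital = np.frombuffer(body[:expected], dtype="<i2").reshape(
            n_records, n_ch, samples_per_record
        )
    gain = (pmax - pmin) / (dmax - dmin)
    physical = (
        (digital.astype(float) - dmin[None, :, None]) * gain[None, :, None]
        + pmin[None, :, None]
    )
    signals = physical.transpose(1, 0, 2).reshape(n_ch, -1)
    return EDFRecording(
        signals=signals, fs=fs, channel_names=names, physical_dimension=phys_dim
    )
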