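"""Minimal EDF (European Data Format) writer.

Writes plain EDF: fixed 256-byte header, 256 bytes per signal, then 1-second
data records of little-endian 16-bit integers. Physical units are microvolts
with a symmetric physical range, so the quantisation step is
``2 * phys_max / 65535``. Only what the package's own reader consumes is
supported (no EDF+ annotation channel; events travel in a plain-text sidecar).
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_edf", "EDF_PHYS_MAX"]

#: default symmetric physical range, µV; generous enough for artifact spikes
EDF_PHYS_MAX = 2000.0

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} ascii bytes")
    return s.ljust(width).encode("ascii")


def write_edf(
    path,
    samples_uv: np.ndarray,
    fs: float,
    channel_labels,
    *,
    phys_max: float = EDF_PHYS_MAX,
    patient_id: str = "X",
    recording_id: str = "edsleep synthetic",
) -> None:
    """Write ``samples_uv`` (channels x time, µV) to ``path`` as 16-bit EDF.

    The recording is truncated to a whole number of 1-second records and the
    sampling rate must be an integer. Samples outside ±``phys_max`` are
    clipped.
    """
    samples_uv = np.asarray(samples_uv, dtype=float)
    if samples_uv.ndim != 2:
        raise ValueError("samples must be a 2-D channels x time array")
    n_ch, n_samp = samples_uv.shape
    if len(channel_labels) != n_ch:
        raise ValueError(
            f"{len(channel_labels)} labels for {n_ch} channels"
        )
    if fs <= 0 or abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_rec = n_samp // fs
    if n_rec < 1:
        raise ValueError("recording shorter than one 1-second data record")

    header = b"".join(
        [
            _field("0", 8),
            _field(patient_id, 80),
            _field(recording_id, 80),
            _field("01.01.01", 8),
            _field("00.00.00", 8),
            _field(str(256 * (1 + n_ch)), 8),
            _field("", 44),
            _field(str(n_rec), 8),
            _field("1", 8),
            _field(str(n_ch), 4),
        ]
    )
    per_signal = [
        b"".join(_field(lab, 16) for lab in channel_labels),
        b"".join(_field("", 80) for _ in range(n_ch)),
        b"".join(_field("uV", 8) for _ in range(n_ch)),
        b"".join(_field(f"{-phys_max:g}", 8) for _ in range(n_ch)),
        b"".join(_field(f"{phys_max:g}", 8) for _ in range(n_ch)),
        b"".join(_field(str(_DIG_MIN), 8) for _ in range(n_ch)),
        b"".join(_field(str(_DIG_MAX), 8) for _ in range(n_ch)),
        b"".join(_field("", 80) for _ in range(n_ch)),
        b"".join(_field(str(fs), 8) for _ in range(n_ch)),
        b"".join(_field("", 32) for _ in range(n_ch)),
    ]

    gain = (_DIG_MAX - _DIG_MIN) / (2.0 * phys_max)
    clipped = np.clip(samples_uv[:, : n_rec * fs], -phys_max, phys_max)
    digital = np.round((clipped + phys_max) * gain + _DIG_MIN).astype("<i2")
    # records are stored signal-major inside each 1-s record
    records = digital.reshape(n_ch, n_rec, fs).transpose(1, 0, 2)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b"".join(per_signal))
        fh.write(records.tobytes())
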