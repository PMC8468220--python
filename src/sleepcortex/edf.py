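"""EDF input/output for PSG recordings.

Reading goes through mne's native EDF reader.  Writing is a minimal EDF
(16-bit) implementation: fixed metadata, one-second data records, a fixed
symmetric physical range, little-endian int16 samples -- sufficient for
synthetic recordings and byte-reproducible for a fixed input.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import FormatError, SpecError
from .spectral import PsgRecording, canonical_channel

#: Fixed physical range of the writer (uV); 0.061 uV quantization step.
PHYS_RANGE_UV = 2000.0
DIG_MIN, DIG_MAX = -32768, 32767


def _pad(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        raise SpecError(f"EDF header field {value!r} exceeds {width} bytes")
    return b.ljust(width)


def write_edf(rec: PsgRecording, path: str | Path, patient_id: str = "X") -> None:
    """Write a recording as 16-bit EDF with 1-s data records.

    The sampling rate must be an integer and the signal length a whole
    number of seconds.  Amplitudes are clipped to +-2000 uV.
    """
    sfreq = rec.sfreq
    if abs(sfreq - round(sfreq)) > 1e-9:
        raise SpecError("EDF writer requires an integer sampling rate")
    spr = int(round(sfreq))  # samples per 1-s record
    if rec.n_samples % spr != 0:
        raise SpecError("signal length must be a whole number of seconds")
    n_records = rec.n_samples // spr
    ns = len(rec.labels)

    header = b"".join(
        [
            _pad("0", 8),
            _pad(patient_id, 80),
            _pad("Startdate 01-JAN-2000 synthetic", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (ns + 1)), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(ns), 4),
        ]
    )
    fields = [
        [_pad(lab, 16) for lab in rec.labels],
        [_pad("AgAgCl electrode", 80)] * ns,
        [_pad("uV", 8)] * ns,
        [_pad(str(-PHYS_RANGE_UV), 8)] * ns,
        [_pad(str(PHYS_RANGE_UV), 8)] * ns,
        [_pad(str(DIG_MIN), 8)] * ns,
        [_pad(str(DIG_MAX), 8)] * ns,
        [_pad("", 80)] * ns,
        [_pad(str(spr), 8)] * ns,
        [_pad("", 32)] * ns,
    ]
    sig_header = b"".join(b"".join(col) for col in fields)

    scale = (DIG_MAX - DIG_MIN) / (2 * PHYS_RANGE_UV)
    x = np.clip(np.asarray(rec.data, dtype=np.float64), -PHYS_RANGE_UV, PHYS_RANGE_UV)
    digital = np.rint((x + PHYS_RANGE_UV) * scale + DIG_MIN).astype("<i2")
    # records: (n_records, ns, spr) interleaving channels per second
    records = digital.reshape(ns, n_records, spr).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        fh.write(records.tobytes())


def read_edf(path: str | Path, canonicalize: bool = True) -> PsgRecording:
    """Read an EDF/EDF+ file into a :class:`PsgRecording` (uV).

    Channel labels are mapped to canonical 10-20 names when possible
    (case-insensitive; T7/T8/P7/P8 are accepted as T3/T4/T5/T6); unmapped
    channels keep their original label.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="ERROR")
    data = raw.get_data(units="uV")
    labels = []
    for lab in raw.ch_names:
        canon = canonical_channel(lab) if canonicalize else None
        labels.append(canon if canon is not None else lab.strip())
    if len(set(labels)) != len(labels):
        raise FormatError(f"{path}: duplicate channel labels after canonicalization")
    return PsgRecording(tuple(labels), float(raw.info["sfreq"]), np.asarray(data))
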