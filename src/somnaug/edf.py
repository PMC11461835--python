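"""Minimal 16-bit EDF (European Data Format) reader/writer.

EDF is the distribution format of public polysomnography archives.  A file
is a fixed 256-byte ASCII header, 256 ASCII bytes per signal, then data
records of little-endian int16 samples.  Physical values are mapped
linearly between the per-signal physical and digital ranges, so a
write/read round-trip is exact up to one quantization step.

All signals written to one file must share sampling rate and length.
Records are one second long when the length divides evenly, otherwise a
single record holding the whole trace is used (the record duration field
carries the true duration).
"""

from __future__ import annotations

import datetime as _dt
import os

import numpy as np

from .meta import EEGSignal, RecordingMeta


class EdfFormatError(ValueError):
    """Malformed EDF content; carries the byte offset of the bad field."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at byte offset {offset})")
        self.offset = offset


def _field(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {value!r} > {width} bytes")
    return b.ljust(width)


def write_edf(signals: list[EEGSignal] | EEGSignal, path: str | os.PathLike) -> None:
    """Write signals as channels of one 16-bit EDF file."""
    if isinstance(signals, EEGSignal):
        signals = [signals]
    if not signals:
        raise ValueError("no signals to write")
    fs = signals[0].fs
    n = len(signals[0])
    for s in signals:
        if s.fs != fs or len(s) != n:
            raise ValueError("all channels must share sampling rate and length")
        if not np.all(np.isfinite(s.samples)):
            raise ValueError("cannot write non-finite samples")

    spr_1s = int(round(fs))
    if abs(spr_1s - fs) < 1e-9 and n % spr_1s == 0:
        n_records, spr, rec_dur = n // spr_1s, spr_1s, 1.0
    else:
        n_records, spr, rec_dur = 1, n, n / fs

    ns = len(signals)
    header_bytes = 256 * (1 + ns)
    now = _dt.datetime(2000, 1, 1)
    patient = " ".join(
        (s.meta.subject_id if s.meta else f"ch{i}") for i, s in enumerate(signals)
    )[:80]

    head = b"".join(
        [
            _field("0", 8),
            _field(patient, 80),
            _field("somnaug synthetic cohort", 80),
            _field(now.strftime("%d.%m.%y"), 8),
            _field(now.strftime("%H.%M.%S"), 8),
            _field(str(header_bytes), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field(f"{rec_dur:.7g}"[:8], 8),
            _field(str(ns), 4),
        ]
    )

    pmins, pmaxs, scaled = [], [], []
    for s in signals:
        amax = float(np.max(np.abs(s.samples)))
        amax = amax if amax > 0 else 1.0
        pmin, pmax = -amax, amax
        dig = np.round(
            (s.samples - pmin) / (pmax - pmin) * 65535.0 - 32768.0
        ).astype("<i2")
        pmins.append(pmin)
        pmaxs.append(pmax)
        scaled.append(dig)

    def _cols(values: list[str], width: int) -> bytes:
        return b"".join(_field(v, width) for v in values)

    labels = [
        (s.meta.channel if s.meta else "EEG")[:16] for s in signals
    ]
    head += _cols(labels, 16)
    head += _cols([""] * ns, 80)                       # transducer
    head += _cols(["uV"] * ns, 8)                      # physical dimension
    head += _cols([f"{p:.6g}"[:8] for p in pmins], 8)
    head += _cols([f"{p:.6g}"[:8] for p in pmaxs], 8)
    head += _cols(["-32768"] * ns, 8)
    head += _cols(["32767"] * ns, 8)
    head += _cols([""] * ns, 80)                       # prefiltering
    head += _cols([str(spr)] * ns, 8)
    head += _cols([""] * ns, 32)

    with open(path, "wb") as fh:
        fh.write(head)
        for r in range(n_records):
            for dig in scaled:
                fh.write(dig[r * spr : (r + 1) * spr].tobytes())


def _parse(buf: bytes, offset: int, width: int, kind, what: str):
    raw = buf[offset : offset + width]
    if len(raw) < width:
        raise EdfFormatError(f"truncated header, missing {what}", offset)
    text = raw.decode("ascii", errors="replace").strip()
    if kind is str:
        return text
    try:
        return kind(text)
    except ValueError:
        raise EdfFormatError(f"unparseable {what}: {text!r}", offset) from None


def read_edf(path: str | os.PathLike) -> list[EEGSignal]:
    """Read all channels of an EDF file as ``EEGSignal`` objects."""
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < 256:
        raise EdfFormatError("file shorter than the 256-byte EDF header", 0)
    version = _parse(buf, 0, 8, str, "version")
    if version != "0":
        raise EdfFormatError(f"unsupported EDF version {version!r}", 0)
    header_bytes = _parse(buf, 184, 8, int, "header byte count")
    n_records = _parse(buf, 236, 8, int, "number of data records")
    rec_dur = _parse(buf, 244, 8, float, "record duration")
    ns = _parse(buf, 252, 4, int, "signal count")
    if ns < 1:
        raise EdfFormatError(f"signal count must be >= 1, got {ns}", 252)
    if rec_dur <= 0:
        raise EdfFormatError(f"record duration must be positive, got {rec_dur}", 244)
    if header_bytes != 256 * (1 + ns):
        raise EdfFormatError(
            f"header byte count {header_bytes} != 256*(1+{ns})", 184
        )

    def col(block: int, width: int, kind, what: str) -> list:
        base = 256 + block
        return [
            _parse(buf, base + i * width, width, kind, f"{what}[{i}]")
            for i in range(ns)
        ]

    off = 0
    labels = col(off, 16, str, "label"); off += ns * 16
    off += ns * 80                                  # transducer
    off += ns * 8                                   # physical dimension
    pmins = col(off, 8, float, "physical min"); off += ns * 8
    pmaxs = col(off, 8, float, "physical max"); off += ns * 8
    dmins = col(off, 8, int, "digital min"); off += ns * 8
    dmaxs = col(off, 8, int, "digital max"); off += ns * 8
    off += ns * 80                                  # prefiltering
    sprs = col(off, 8, int, "samples per record"); off += ns * 8

    data = np.frombuffer(buf, dtype="<i2", offset=header_bytes)
    rec_len = sum(sprs)
    if len(data) < n_records * rec_len:
        raise EdfFormatError(
            f"data area holds {len(data)} samples, "
            f"expected {n_records * rec_len}",
            header_bytes,
        )
    data = data[: n_records * rec_len].reshape(n_records, rec_len)

    signals = []
    start = 0
    for i in range(ns):
        spr = sprs[i]
        dig = data[:, start : start + spr].reshape(-1).astype(np.float64)
        start += spr
        gain = (pmaxs[i] - pmins[i]) / (dmaxs[i] - dmins[i])
        phys = (dig - dmins[i]) * gain + pmins[i]
        fs = spr / rec_dur
        meta = RecordingMeta(
            subject_id=f"edf{i}", group="healthy", fs=fs, channel=labels[i]
        )
        signals.append(EEGSignal(phys, fs, meta))
    return signals


def quantization_step(signal: EEGSignal) -> float:
    """The physical value of one digital unit as written by ``write_edf``."""
    amax = float(np.max(np.abs(signal.samples)))
    amax = amax if amax > 0 else 1.0
    return 2.0 * amax / 65535.0
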