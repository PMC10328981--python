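"""Minimal WFDB codec: text headers, format-16 signals, MIT annotations.

Supports the subset of the PhysioNet WFDB conventions this package needs:

* ``.hea`` record headers (record line + one signal line per channel),
* ``.dat`` signal files in format 16 (interleaved little-endian int16,
  physical value = (adu - baseline) / gain),
* ``.atr``-style annotation files in the MIT byte format (6-bit type code +
  10-bit time increment per 16-bit word, with the SKIP pseudo-annotation
  carrying a 32-bit interval for gaps >= 1024 samples).

Only single-segment records are handled; formats other than 16 are refused.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

# MIT annotation type codes <-> display symbols (beat subset + common events)
CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 25: "x", 34: "|",
    35: "f", 38: "(",
}
SYMBOL_TO_CODE = {s: c for c, s in CODE_TO_SYMBOL.items()}

#: Type codes that denote a heartbeat (QRS) annotation.
BEAT_CODES = frozenset({1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 25, 34, 35, 38})

_SKIP = 59
_NUM = 60
_SUB = 61
_CHN = 62
_AUX = 63


@dataclass
class WfdbHeader:
    record_name: str
    n_sig: int
    fs: float
    n_samples: int
    dat_file: str
    gains: list[float] = field(default_factory=list)
    baselines: list[int] = field(default_factory=list)
    sig_names: list[str] = field(default_factory=list)


def read_header(path: str | Path) -> WfdbHeader:
    path = Path(path)
    lines = [
        ln.strip()
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec_line = lines[0].split()
    record_name = rec_line[0].split("/")[0]
    n_sig = int(rec_line[1])
    fs = float(rec_line[2]) if len(rec_line) > 2 else 250.0
    n_samples = int(rec_line[3]) if len(rec_line) > 3 else 0
    hdr = WfdbHeader(record_name, n_sig, fs, n_samples, dat_file="")
    for ln in lines[1:1 + n_sig]:
        tok = ln.split()
        fname, fmt = tok[0], tok[1]
        if fmt.split("x")[0] != "16":
            raise ValueError(f"unsupported WFDB signal format {fmt!r} (only 16)")
        gain_tok = tok[2] if len(tok) > 2 else "200"
        gain_part = gain_tok.split("/")[0]
        if "(" in gain_part:
            gain_str, base_str = gain_part[:-1].split("(")
            baseline = int(base_str)
        else:
            gain_str = gain_part
            baseline = int(tok[4]) if len(tok) > 4 else 0
        gain = float(gain_str) if float(gain_str) != 0 else 200.0
        hdr.dat_file = fname
        hdr.gains.append(gain)
        hdr.baselines.append(baseline)
        hdr.sig_names.append(tok[8] if len(tok) > 8 else f"sig{len(hdr.sig_names)}")
    return hdr


def read_signal(header_path: str | Path) -> tuple[WfdbHeader, np.ndarray]:
    """Read a format-16 record; returns (header, physical array (n, n_sig))."""
    header_path = Path(header_path)
    hdr = read_header(header_path)
    raw = np.fromfile(header_path.parent / hdr.dat_file, dtype="<i2")
    usable = (raw.size // hdr.n_sig) * hdr.n_sig
    adu = raw[:usable].reshape(-1, hdr.n_sig).astype(float)
    if hdr.n_samples:
        adu = adu[: hdr.n_samples]
    gains = np.asarray(hdr.gains, dtype=float)
    baselines = np.asarray(hdr.baselines, dtype=float)
    return hdr, (adu - baselines) / gains


def write_record(
    directory: str | Path,
    record_name: str,
    signal: np.ndarray,
    fs: float,
    gain: float = 200.0,
    sig_names: list[str] | None = None,
) -> Path:
    """Write physical signal (n,) or (n, n_sig) as a format-16 WFDB record."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    if signal.shape[0] < signal.shape[1]:
        signal = signal.T
    n, n_sig = signal.shape
    adu = np.clip(np.round(signal * gain), -32768, 32767).astype("<i2")
    (directory / f"{record_name}.dat").write_bytes(adu.tobytes())
    names = sig_names or [f"sig{i}" for i in range(n_sig)]
    fs_str = f"{fs:g}"
    lines = [f"{record_name} {n_sig} {fs_str} {n}"]
    for i in range(n_sig):
        lines.append(
            f"{record_name}.dat 16 {gain:g}(0)/mV 12 0 {int(adu[0, i])} 0 0 {names[i]}"
        )
    hea = directory / f"{record_name}.hea"
    hea.write_text("\n".join(lines) + "\n")
    return hea


def read_annotations(path: str | Path) -> list[tuple[int, str]]:
    """Decode an MIT-format annotation file to [(sample_index, symbol), ...].

    Only beat annotations (type code in :data:`BEAT_CODES`) are returned;
    NUM/SUB/CHN/AUX pseudo-annotations are consumed and ignored.
    """
    data = Path(path).read_bytes()
    out: list[tuple[int, str]] = []
    t = 0
    i = 0
    n = len(data)
    while i + 1 < n:
        word = data[i] | (data[i + 1] << 8)
        i += 2
        code = word >> 10
        interval = word & 0x3FF
        if code == 0 and interval == 0:
            break
        if code == _SKIP:
            if i + 3 >= n:
                break
            high = struct.unpack_from("<h", data, i)[0]
            low = struct.unpack_from("<H", data, i + 2)[0]
            i += 4
            t += (high << 16) | low
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        if code == _AUX:
            i += interval + (interval & 1)
            continue
        t += interval
        if code in BEAT_CODES:
            out.append((t, CODE_TO_SYMBOL.get(code, "?")))
    return out


def write_annotations(path: str | Path, annotations: list[tuple[int, str]]) -> Path:
    """Encode [(sample_index, symbol), ...] in the MIT annotation format."""
    path = Path(path)
    buf = bytearray()
    prev = 0
    for idx, symbol in annotations:
        idx = int(idx)
        if idx < prev:
            raise ValueError("annotation indices must be non-decreasing")
        code = SYMBOL_TO_CODE.get(symbol, 13)  # unknown beat symbol -> Q
        delta = idx - prev
        if delta > 1023:
            buf += struct.pack("<H", _SKIP << 10)
            buf += struct.pack("<h", delta >> 16)
            buf += struct.pack("<H", delta & 0xFFFF)
            delta = 0
        buf += struct.pack("<H", (code << 10) | delta)
        prev = idx
    buf += struct.pack("<H", 0)
    path.write_bytes(bytes(buf))
    return path
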