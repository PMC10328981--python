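"""Record I/O: WFDB/CSV ingest, resampling, and boundary serialisation.

All internal processing runs at a single rate (360 Hz by default, the rate
the detector's fixed 512-sample input is sized for); records sampled at a
different native rate are resampled on load and the original rate is kept
on the record so outputs can be mapped back.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from . import wfdb_lite
from ._util import round_half_up

logger = logging.getLogger(__name__)

#: The processing rate everything downstream assumes (Hz).
PROCESSING_FS = 360.0


@dataclass(frozen=True)
class AnnotatedBeat:
    """One annotated heartbeat: 0-based sample position + beat-type code."""

    sample_index: int
    label: str = "N"

    def __post_init__(self):
        if self.sample_index < 0:
            raise ValueError("annotation index must be >= 0")


@dataclass(frozen=True)
class EcgRecord:
    """A single-lead ECG trace with its sampling rate and optional beat labels."""

    record_id: str
    fs: float
    signal: np.ndarray
    native_fs: float | None = None
    annotations: list[AnnotatedBeat] = field(default_factory=list)

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.signal.ndim != 1 or self.signal.size < 1:
            raise ValueError("signal must be a non-empty 1-D array")
        for a in self.annotations:
            if not 0 <= a.sample_index < self.signal.size:
                raise ValueError(f"annotation index {a.sample_index} outside record")

    def __len__(self) -> int:
        return int(self.signal.size)

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    def annotation_indices(self) -> np.ndarray:
        return np.array([a.sample_index for a in self.annotations], dtype=np.int64)


@dataclass(frozen=True)
class BeatBoundaries:
    """Per-beat segmentation output.

    ``bl``/``br`` are the immediate (method-I) margins placed around the
    critical point as ratios of the mean cp interval; ``bl2``/``br2`` are
    the retrospective (method-II) margins computed from the neighbouring
    critical points once the next beat is known (absent for the final beat).
    Half-open ``[bl, br)`` sample conventions, 0-based.
    """

    j: int
    cp: int
    bl: int
    br: int
    bl2: int | None = None
    br2: int | None = None

    def __post_init__(self):
        if not self.bl < self.cp < self.br:
            raise ValueError("method-I margins must bracket the critical point")
        if self.bl2 is not None and self.br2 is not None and not self.bl2 < self.br2:
            raise ValueError("method-II margins must be ordered")


def read_record(
    path: str | Path,
    lead: int = 0,
    fs: float | None = None,
    annotation_ext: str = "atr",
) -> EcgRecord:
    """Read one ECG lead from a WFDB header (.hea) or a one-column CSV.

    For CSV input ``fs`` is required (the file has no rate metadata).  For
    WFDB input an annotation file with the given extension is loaded from
    the same directory when present; an unreadable annotation file leaves
    the record unannotated with a logged warning.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        if fs is None:
            raise ValueError("fs must be given for CSV input")
        df = pd.read_csv(path, header=None, comment="#")
        first = df.iloc[0, 0]
        if isinstance(first, str):
            df = pd.read_csv(path, comment="#")
        signal = np.asarray(df.iloc[:, lead], dtype=float)
        return EcgRecord(record_id=path.stem, fs=float(fs), signal=signal,
                         native_fs=float(fs))
    if path.suffix == "":
        path = path.with_suffix(".hea")
    hdr, phys = wfdb_lite.read_signal(path)
    if not 0 <= lead < hdr.n_sig:
        raise ValueError(f"lead {lead} not present (record has {hdr.n_sig})")
    signal = phys[:, lead]
    annotations: list[AnnotatedBeat] = []
    ann_path = path.with_suffix(f".{annotation_ext}")
    if ann_path.exists():
        try:
            raw = wfdb_lite.read_annotations(ann_path)
            annotations = [
                AnnotatedBeat(idx, sym) for idx, sym in raw if 0 <= idx < signal.size
            ]
        except Exception as exc:  # corrupt annotation file is non-fatal
            logger.warning("could not read annotations %s: %s", ann_path, exc)
    return EcgRecord(record_id=hdr.record_name, fs=hdr.fs, signal=signal,
                     native_fs=hdr.fs, annotations=annotations)


def resample_to(rec: EcgRecord, target_fs: float) -> EcgRecord:
    """Polyphase-resample a record to ``target_fs``.

    Annotation indices are rescaled by the exact rational ratio and rounded
    half-up; ``native_fs`` is preserved so indices can be mapped back.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if target_fs == rec.fs:
        return rec
    ratio = Fraction(target_fs / rec.fs).limit_denominator(10000)
    signal = resample_poly(rec.signal, ratio.numerator, ratio.denominator)
    n_out = int(round(len(rec) * target_fs / rec.fs))
    if signal.size > n_out:
        signal = signal[:n_out]
    elif signal.size < n_out:
        signal = np.pad(signal, (0, n_out - signal.size), mode="edge")
    anns = [
        replace(a, sample_index=min(round_half_up(a.sample_index * target_fs / rec.fs),
                                    n_out - 1))
        for a in rec.annotations
    ]
    return EcgRecord(record_id=rec.record_id, fs=float(target_fs), signal=signal,
                     native_fs=rec.native_fs if rec.native_fs is not None else rec.fs,
                     annotations=anns)


_COLUMNS = ["j", "cp", "bl", "br", "bl2", "br2"]


def write_boundaries(
    beats: list[BeatBoundaries],
    path: str | Path,
    fs: float = PROCESSING_FS,
    native_fs: float | None = None,
    constants: dict | None = None,
) -> Path:
    """Write per-beat boundaries as CSV plus a JSON sidecar of the run config.

    Missing method-II margins (the final beat) are written as empty cells.
    """
    path = Path(path)
    cps = [b.cp for b in beats]
    if cps != sorted(cps):
        raise ValueError("beats must be sorted by cp")
    rows = [
        {"j": b.j, "cp": b.cp, "bl": b.bl, "br": b.br,
         "bl2": b.bl2 if b.bl2 is not None else pd.NA,
         "br2": b.br2 if b.br2 is not None else pd.NA}
        for b in beats
    ]
    df = pd.DataFrame(rows, columns=_COLUMNS)
    df.to_csv(path, index=False)
    sidecar = {
        "fs": fs,
        "native_fs": native_fs if native_fs is not None else fs,
        "n_beats": len(beats),
        "constants": constants or {},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_boundaries(path: str | Path) -> list[BeatBoundaries]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        out.append(BeatBoundaries(
            j=int(r["j"]), cp=int(r["cp"]), bl=int(r["bl"]), br=int(r["br"]),
            bl2=None if pd.isna(r["bl2"]) else int(r["bl2"]),
            br2=None if pd.isna(r["br2"]) else int(r["br2"]),
        ))
    return out
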