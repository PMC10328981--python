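"""Training-set construction from annotated beat triplets.

For each annotated heartbeat with a left and right neighbour, the local
geometry (inter-beat distances d1, d2 and the main-beat length
``s = 0.5*d1 + 0.6*d2``) defines a main segment around the central critical
point.  From it, 12 positive examples (the main segment, six +/-4/8/12%-of-s
shifted copies, five symmetrically end-trimmed copies) and 12 negative
examples (incomplete halves, extreme shifts, and spans covering two
critical points) are cut.  Every eligible beat thus contributes exactly
24 class-balanced examples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import EcgRecord
from .prep import DEFAULT_M, prepare
from ._util import round_half_up

logger = logging.getLogger(__name__)

VB = 1      # valid-beat label
NVB = 0     # non-valid-beat label

POSITIVE_SHIFT_FRACTIONS = (0.04, 0.08, 0.12)
TRIM_FRACTIONS = (0.05, 0.10, 0.15, 0.20, 0.25)
NEGATIVE_SHIFT_FRACTIONS = (0.45, 0.65)
TWO_CP_PAD_FRACTIONS = (0.15, 0.05)


@dataclass(frozen=True)
class TripletGeometry:
    """Geometry derived from a (left, main, right) critical-point triplet."""

    cpl: int
    cpm: int
    cpr: int
    d1: int
    d2: int
    s: int
    bl: int
    br: int
    tl: int
    tr: int


@dataclass(frozen=True)
class SegmentExample:
    values: np.ndarray
    i: int            # variant index, 1..24
    j: int            # source beat ordinal within its record
    label: int        # VB or NVB


def triplet_geometry(cpl: int, cpm: int, cpr: int) -> TripletGeometry:
    """Compute d1, d2, s and the main-beat margins/trim points.

    The main segment of length ``s`` is anchored with its left margin 45%
    of d1 before the central point (left-short/right-long placement), and
    the trimming points sit one 10%-of-s offset inside the outer points.
    """
    if not cpl < cpm < cpr:
        raise ValueError("critical points must be strictly increasing")
    d1 = cpm - cpl
    d2 = cpr - cpm
    s = round_half_up(0.5 * d1 + 0.6 * d2)
    bl = cpm - round_half_up(0.45 * d1)
    br = bl + s
    off = round_half_up(0.1 * s)
    return TripletGeometry(cpl=cpl, cpm=cpm, cpr=cpr, d1=d1, d2=d2, s=s,
                           bl=bl, br=br, tl=cpl + off, tr=cpr - off)


def _slice(rec: EcgRecord, lo: int, hi: int, M: int) -> np.ndarray:
    """Clip [lo, hi) to the record and to length M (kept centred on clip)."""
    lo_c, hi_c = max(lo, 0), min(hi, len(rec))
    if lo_c != lo or hi_c != hi:
        logger.debug("segment [%d, %d) clipped to record bounds", lo, hi)
    if hi_c - lo_c > M:
        excess = (hi_c - lo_c) - M
        lo_c += excess // 2
        hi_c = lo_c + M
    if hi_c <= lo_c:      # fully outside the record: degenerate 1-sample stub
        lo_c = min(max(lo, 0), len(rec) - 1)
        hi_c = lo_c + 1
    return rec.signal[lo_c:hi_c].copy()


def make_positives(rec: EcgRecord, g: TripletGeometry, j: int = 0,
                   M: int = DEFAULT_M) -> list[SegmentExample]:
    """The 12 valid-beat variants of the main segment ``[bl, br)``."""
    windows: list[tuple[int, int]] = [(g.bl, g.br)]
    for frac in POSITIVE_SHIFT_FRACTIONS:
        sh = round_half_up(frac * g.s)
        windows.append((g.bl + sh, g.br + sh))
        windows.append((g.bl - sh, g.br - sh))
    for frac in TRIM_FRACTIONS:
        tr = round_half_up(frac * g.s)
        windows.append((g.bl + tr, g.br - tr))
    return [
        SegmentExample(values=_slice(rec, lo, hi, M), i=i, j=j, label=VB)
        for i, (lo, hi) in enumerate(windows, start=1)
    ]


def make_negatives(rec: EcgRecord, g: TripletGeometry, j: int = 0,
                   M: int = DEFAULT_M) -> list[SegmentExample]:
    """The 12 non-valid-beat variants built from the same triplet.

    Three families of four: incomplete beats cut at (or 5%-of-s away from)
    the central point, extreme +/-45%/65%-of-s shifts of the main segment,
    and spans placed over a pair of critical points.
    """
    near = round_half_up(0.05 * g.s)
    windows: list[tuple[int, int]] = [
        (g.bl, g.cpm),                  # left half, cut exactly at cpm
        (g.cpm, g.br),                  # right half
        (g.bl, g.cpm - near),           # left part, cut short of cpm
        (g.cpm + near, g.br),           # right part, cut past cpm
    ]
    for frac in NEGATIVE_SHIFT_FRACTIONS:
        sh = round_half_up(frac * g.s)
        windows.append((g.bl + sh, g.br + sh))
        windows.append((g.bl - sh, g.br - sh))
    for frac in TWO_CP_PAD_FRACTIONS:
        pad = max(round_half_up(frac * g.s), 1)
        windows.append((g.cpl - pad, g.cpm + pad))
        windows.append((g.cpm - pad, g.cpr + pad))
    return [
        SegmentExample(values=_slice(rec, lo, hi, M), i=i, j=j, label=NVB)
        for i, (lo, hi) in enumerate(windows, start=13)
    ]


def beat_examples(rec: EcgRecord, M: int = DEFAULT_M) -> list[SegmentExample]:
    """All 24·(B-2) examples of a record (first/last beats have no triplet)."""
    idx = rec.annotation_indices()
    out: list[SegmentExample] = []
    for j in range(1, len(idx) - 1):
        g = triplet_geometry(int(idx[j - 1]), int(idx[j]), int(idx[j + 1]))
        out.extend(make_positives(rec, g, j=j, M=M))
        out.extend(make_negatives(rec, g, j=j, M=M))
    return out


@dataclass
class BeatDataset:
    """Prepared training matrix with per-example provenance and fold labels."""

    X: np.ndarray                 # (n, M) float32, aligned + scaled
    y: np.ndarray                 # (n,) int8, VB/NVB
    record_id: np.ndarray         # (n,) unicode
    fold: np.ndarray              # (n,) int16
    i: np.ndarray                 # (n,) int16 variant index
    j: np.ndarray                 # (n,) int32 beat ordinal
    M: int = DEFAULT_M

    def __len__(self) -> int:
        return self.X.shape[0]

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("X", data=self.X, compression="gzip")
            f.create_dataset("y", data=self.y)
            f.create_dataset("record_id",
                             data=np.char.encode(self.record_id.astype(str)))
            f.create_dataset("fold", data=self.fold)
            f.create_dataset("i", data=self.i)
            f.create_dataset("j", data=self.j)
            f.attrs["M"] = self.M

    @classmethod
    def load(cls, path) -> "BeatDataset":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                X=f["X"][:], y=f["y"][:],
                record_id=np.char.decode(f["record_id"][:]),
                fold=f["fold"][:], i=f["i"][:], j=f["j"][:],
                M=int(f.attrs["M"]),
            )


def assign_folds(record_ids: list[str], k: int,
                 fold_table: dict[str, int] | None = None) -> dict[str, int]:
    """Record-wise fold assignment: explicit table, else balanced round-robin
    over the sorted record ids (deterministic; 10 records + k=10 gives one
    record per fold)."""
    if fold_table is not None:
        missing = [r for r in record_ids if r not in fold_table]
        if missing:
            raise ValueError(f"fold table missing records: {missing}")
        return {r: int(fold_table[r]) % k for r in record_ids}
    return {r: rank % k for rank, r in enumerate(sorted(set(record_ids)))}


def build_dataset(records: list[EcgRecord], folds: int = 10,
                  M: int = DEFAULT_M,
                  fold_table: dict[str, int] | None = None) -> BeatDataset:
    """Augment, align and scale every eligible beat of every record.

    Records with fewer than three annotated beats are skipped with a
    warning; each surviving record belongs to exactly one fold.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    usable = []
    for rec in records:
        if len(rec.annotations) < 3:
            logger.warning("record %s has < 3 beats; skipped", rec.record_id)
            continue
        usable.append(rec)
    if not usable:
        raise ValueError("no record has enough annotated beats")
    fold_of = assign_folds([r.record_id for r in usable], folds, fold_table)
    X, y, rid, fold, ii, jj = [], [], [], [], [], []
    for rec in usable:
        for ex in beat_examples(rec, M=M):
            X.append(prepare(ex.values, M).values.astype(np.float32))
            y.append(ex.label)
            rid.append(rec.record_id)
            fold.append(fold_of[rec.record_id])
            ii.append(ex.i)
            jj.append(ex.j)
    return BeatDataset(
        X=np.asarray(X, dtype=np.float32),
        y=np.asarray(y, dtype=np.int8),
        record_id=np.asarray(rid),
        fold=np.asarray(fold, dtype=np.int16),
        i=np.asarray(ii, dtype=np.int16),
        j=np.asarray(jj, dtype=np.int32),
        M=M,
    )
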