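"""Fixed-length alignment and scaling of ECG segments.

Every candidate segment handed to the beat detector — whether an augmented
training example or a window sliced off the raw signal — is first padded to
a fixed length ``M`` (default 512 samples, about 1.4 s at 360 Hz) with the
source centred and the slack filled by repeating the segment's endpoint
values, then min–max scaled to [0, 1].  Centring uses a ceil split, so when
the slack is odd the extra padding sample goes on the left.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: Fixed detector input length in samples; 512/360 Hz ~ 1422 ms.
DEFAULT_M = 512


@dataclass(frozen=True)
class AlignedVector:
    """A detector-ready segment: length ``M``, centred, scaled to [0, 1]."""

    values: np.ndarray
    source_len: int

    @property
    def M(self) -> int:
        return self.values.shape[0]

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.M


def align(v: np.ndarray, M: int = DEFAULT_M) -> np.ndarray:
    """Centre ``v`` in a length-``M`` vector, padding with its endpoints.

    The source occupies positions ``[ceil((M-L)/2), ceil((M-L)/2)+L)``;
    samples before it repeat ``v[0]`` and samples after it repeat ``v[-1]``.

    Raises
    ------
    ValueError
        If ``v`` is empty or longer than ``M``.
    """
    v = np.asarray(v, dtype=float).ravel()
    L = v.shape[0]
    if L == 0:
        raise ValueError("cannot align an empty segment")
    if L > M:
        raise ValueError(f"segment length {L} exceeds fixed length M={M}")
    lead = math.ceil((M - L) / 2)
    w = np.empty(M, dtype=float)
    w[:lead] = v[0]
    w[lead:lead + L] = v
    w[lead + L:] = v[-1]
    return w


def minmax(w: np.ndarray) -> np.ndarray:
    """Scale ``w`` to [0, 1]; a constant input maps to all zeros.

    Flatline windows (signal dropouts) must flow through the detector as
    obvious non-beats rather than raising, hence the all-zeros convention
    for zero range.
    """
    w = np.asarray(w, dtype=float).ravel()
    if w.size == 0:
        raise ValueError("cannot scale an empty segment")
    lo = w.min()
    rng = w.max() - lo
    if rng == 0:
        return np.zeros_like(w)
    return (w - lo) / rng


def prepare(v: np.ndarray, M: int = DEFAULT_M) -> AlignedVector:
    """Align then min–max scale a raw segment into an :class:`AlignedVector`."""
    v = np.asarray(v, dtype=float).ravel()
    return AlignedVector(values=minmax(align(v, M)), source_len=v.shape[0])
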