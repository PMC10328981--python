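"""Small shared numeric helpers."""

from __future__ import annotations

import math

import numpy as np


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero toward +inf.

    All sample-index quantities in the package are rounded with this rule
    (banker's rounding would make .5 cases depend on parity).
    """
    return int(math.floor(float(x) + 0.5))


def round_half_up_array(x) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)
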