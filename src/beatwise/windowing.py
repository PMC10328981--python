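"""Adaptive sliding-window beat segmentation — the core algorithm.

A window slides along the ECG; each slice is prepared (centred, padded to
``M``, scaled) and handed to a detector that returns the probability
``P(B)`` that the slice holds one complete, roughly centred heartbeat.
On every confirmed detection the window length, step size, restart
position, plausibility thresholds and the beat boundaries are all
recomputed as fixed ratios of the moving mean critical-point interval
``C̄`` (the mean of the last ``K`` accepted inter-beat intervals), so the
window keeps tracking the local rhythm:

* window length ``ω = η_w·C̄`` and step ``s = η_s·C̄``;
* the next window starts ``η_of·C̄`` past the detected critical point;
* a candidate whose distance to the previous critical point falls below
  ``η_cmin·C̄`` is rejected as a double detection — the window is re-run
  from just past it with tiny steps; one beyond ``η_cmax·C̄`` is segmented
  but excluded from the mean;
* method-I boundaries span ``η_δ·C̄`` split 5:6 around the critical point;
  method-II boundaries of the previous beat are midway (``η_l``/``η_r``)
  to its neighbouring critical points.

Before segmentation starts, an initialisation pass scans the first beats
with a fixed window of half a second, growing it by ``e^0.01`` factors if
the rhythm cannot be acquired, until ``K`` beats have been accepted; those
beats receive no boundaries but seed the interval buffer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import BeatBoundaries, EcgRecord
from .prep import DEFAULT_M, prepare
from ._util import round_half_up


class InitializationError(RuntimeError):
    """The rhythm could not be acquired from the start of the signal."""


@dataclass(frozen=True)
class WindowConstants:
    """The fixed ratios steering the adaptive window (defaults as published)."""

    eta_w: float = 0.9                # window length / mean cp interval
    eta_s: float = 3 * 0.9 / 11       # step size ratio
    eta_of: float = 0.1               # restart offset past the detected cp
    eta_sof: float | None = None      # tiny-step ratio; None -> eta_s / 3
    eta_cmin: float = 0.45            # too-close rejection threshold ratio
    eta_cmax: float = 1.45            # too-far rejection threshold ratio
    eta_delta: float = 0.9            # segment length ratio (safety margin)
    eta_ar: float = 5 / 11            # left share of the segment (5:6 split)
    eta_l: float = 0.5                # method-II left fraction
    eta_r: float = 0.5                # method-II right fraction
    p_b: float = 0.9                  # detection confidence level
    M: int = DEFAULT_M                # fixed detector input length
    K: int = 16                       # intervals in the moving mean
    cp_rule: str = "dominant"         # "dominant" | "literal" extremum rule
    init_window_s: float = 0.5        # initial window, seconds
    init_scan_s: float = 30.0         # rhythm must be acquired within this span
    init_max_restarts: int = 100
    init_max_cv: float = 0.5          # max coefficient of variation at init

    def __post_init__(self):
        if not 0 < self.eta_cmin < 1 < self.eta_cmax:
            raise ValueError("need 0 < eta_cmin < 1 < eta_cmax")
        if not 0 < self.eta_ar < 1:
            raise ValueError("eta_ar must be in (0, 1)")
        if not 0 < self.p_b < 1:
            raise ValueError("p_b must be in (0, 1)")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.cp_rule not in ("dominant", "literal"):
            raise ValueError("cp_rule must be 'dominant' or 'literal'")

    @property
    def tiny_step_ratio(self) -> float:
        return self.eta_sof if self.eta_sof is not None else self.eta_s / 3

    def as_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


class CpStatus(Enum):
    ACCEPTED = "accepted"
    TOO_CLOSE = "too_close"
    TOO_FAR = "too_far"


@dataclass(frozen=True)
class CpCandidate:
    index: int
    degenerate: bool = False
    status: CpStatus | None = None


@dataclass(frozen=True)
class WindowState:
    """All adaptive parameters at one iteration (immutable snapshot)."""

    j: int                      # beats segmented so far
    omega: int                  # window length, samples
    step: int                   # step size, samples
    wst: int                    # window start position
    cbar: float                 # mean cp interval (kept real-valued)
    intervals: tuple            # last <= K accepted intervals
    last_cp: int
    cp_min: int
    cp_max: int
    delta: int                  # relocation offset after a rejected candidate
    small_step: bool = False
    detected: bool = False


def determine_cp(window: np.ndarray, wst: int, rule: str = "dominant") -> CpCandidate:
    """Locate the critical point of a window from its median and extrema.

    ``dominant`` (default) picks the extremum farther from the median —
    the dominant deflection (an upright QRS has its median near baseline,
    far from the R maximum).  ``literal`` picks the nearer extremum.
    Ties break toward the maximum; a constant window is degenerate and
    yields its first sample.
    """
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise ValueError("empty window")
    med = float(np.median(window))
    i_max = int(np.argmax(window))
    i_min = int(np.argmin(window))
    d_max = abs(window[i_max] - med)
    d_min = abs(window[i_min] - med)
    if d_max == d_min == 0:
        return CpCandidate(index=wst, degenerate=True)
    if rule == "dominant":
        idx = i_max if d_max >= d_min else i_min
    else:
        idx = i_max if d_max <= d_min else i_min
    return CpCandidate(index=wst + idx)


def update_mean(intervals, c_j: float, K: int) -> tuple[tuple, float]:
    """Push an accepted interval and return (buffer, mean of last <= K)."""
    if c_j <= 0:
        raise ValueError("intervals must be positive")
    buf = (tuple(intervals) + (float(c_j),))[-K:]
    return buf, float(np.mean(buf))


def _derived(cbar: float, cp: int, cns: WindowConstants):
    # the window can never exceed the detector's fixed input length
    omega = min(max(round_half_up(cns.eta_w * cbar), 2), cns.M)
    step = max(round_half_up(cns.eta_s * cbar), 1)
    wst = cp + max(round_half_up(cns.eta_of * cbar), 1)
    cp_min = round_half_up(cns.eta_cmin * cbar)
    cp_max = round_half_up(cns.eta_cmax * cbar)
    delta = max(round_half_up(cns.eta_of * cbar), 1)
    return omega, step, wst, cp_min, cp_max, delta


def method1_boundaries(cp: int, cbar: float, cns: WindowConstants) -> tuple[int, int]:
    """Immediate margins: length ``round(η_δ·C̄)`` split ``η_ar : 1-η_ar``.

    The length is rounded once and then split, so the segment length is
    exactly ``round(η_δ·C̄)`` and the 5:6 ratio holds within rounding.
    """
    length = max(round_half_up(cns.eta_delta * cbar), 2)
    left = max(round_half_up(cns.eta_ar * length), 1)
    return cp - left, cp - left + length


def method2_boundaries(cp_prev2: int, cp_prev: int, cp_cur: int,
                       cns: WindowConstants) -> tuple[int, int]:
    """Retrospective margins of beat ``j-1`` from its neighbouring cps."""
    if not cp_prev2 < cp_prev < cp_cur:
        raise ValueError("critical points must be strictly increasing")
    bl2 = round_half_up(cp_prev - cns.eta_l * (cp_prev - cp_prev2))
    br2 = round_half_up(cp_prev + cns.eta_r * (cp_cur - cp_prev))
    return bl2, br2


def update_on_detection(state: WindowState, cp: int, cns: WindowConstants,
                        include_in_mean: bool = True
                        ) -> tuple[WindowState, BeatBoundaries]:
    """Confirm a detection at ``cp``: update C̄ (unless the interval was
    rejected as too far), rescale every window parameter, and emit the
    method-I boundaries."""
    if state.cbar <= 0:
        raise ValueError("state has no valid mean cp interval")
    c = cp - state.last_cp
    if include_in_mean:
        intervals, cbar = update_mean(state.intervals, c, cns.K)
    else:
        intervals, cbar = state.intervals, state.cbar
    omega, step, wst, cp_min, cp_max, delta = _derived(cbar, cp, cns)
    bl, br = method1_boundaries(cp, cbar, cns)
    new = replace(state, j=state.j + 1, omega=omega, step=step, wst=wst,
                  cbar=cbar, intervals=intervals, last_cp=cp, cp_min=cp_min,
                  cp_max=cp_max, delta=delta, small_step=False, detected=True)
    return new, BeatBoundaries(j=state.j, cp=cp, bl=bl, br=br)


def update_on_miss(state: WindowState, P: float, cand: CpCandidate | None,
                   cns: WindowConstants) -> WindowState:
    """Advance without confirming a beat.

    Low-confidence windows step forward with everything else unchanged;
    a confident but too-close candidate relocates the window just past the
    faulty point and switches to tiny steps until the next acceptance.
    """
    if P < cns.p_b:
        return replace(state, wst=state.wst + state.step, detected=False)
    if cand is None:
        raise ValueError("a confident miss needs the rejected candidate")
    tiny = max(round_half_up(cns.tiny_step_ratio * state.cbar), 1)
    return replace(state, wst=max(cand.index + state.delta, state.wst + 1),
                   step=tiny, small_step=True, detected=False)


def initialize(signal: np.ndarray, detector, cns: WindowConstants,
               fs: float) -> tuple[WindowState, list[int]]:
    """Acquire the rhythm: collect ``K`` accepted cps without segmenting.

    Runs a fixed window of ``init_window_s`` seconds from the signal
    start; each accepted beat refreshes the running mean (over all
    intervals so far) and rescales the window.  Fails if ``K`` beats are
    not found within ``init_scan_s`` seconds or the collected intervals
    are too dispersed; each failure restarts with the initial window grown
    by ``e^0.01``, up to ``init_max_restarts`` times.
    """
    signal = np.asarray(signal, dtype=float)
    base_omega = cns.init_window_s * fs
    if signal.size < round_half_up(base_omega):
        raise InitializationError("signal shorter than the initial window")
    limit = min(signal.size, round_half_up(cns.init_scan_s * fs))
    for attempt in range(cns.init_max_restarts + 1):
        omega0 = round_half_up(base_omega * math.exp(0.01 * attempt))
        state = _init_pass(signal, detector, cns, omega0, limit)
        if state is not None:
            return state
    raise InitializationError(
        f"no stable rhythm within the first {cns.init_scan_s:g} s "
        f"after {cns.init_max_restarts} window restarts")


def _init_pass(signal, detector, cns, omega0: int, limit: int):
    omega = omega0
    step = max(round_half_up(cns.eta_s / cns.eta_w * omega0), 1)
    offset = max(round_half_up(cns.eta_of * omega0), 1)
    wst = 0
    cps: list[int] = []
    intervals: list[float] = []
    cbar = 0.0
    cp_min = cp_max = None
    while wst + omega <= limit and len(cps) < cns.K:
        x = prepare(signal[wst:wst + omega], cns.M)
        P = detector.predict_beat_proba(x)
        if P < cns.p_b:
            wst += step
            continue
        cand = determine_cp(signal[wst:wst + omega], wst, cns.cp_rule)
        if cand.degenerate:
            wst += step
            continue
        if not cps:
            cps.append(cand.index)
            wst = cand.index + offset
            continue
        c = cand.index - cps[-1]
        if c <= 0 or (cp_min is not None and c < cp_min):
            wst = max(cand.index + offset, wst + 1)
            continue
        if cp_max is not None and c > cp_max:
            cps.append(cand.index)          # a beat, but not in the mean
            wst = cand.index + offset
            continue
        intervals.append(float(c))
        cps.append(cand.index)
        cbar = float(np.mean(intervals))    # running mean over all so far
        omega = min(max(round_half_up(cns.eta_w * cbar), 2), cns.M)
        step = max(round_half_up(cns.eta_s * cbar), 1)
        offset = max(round_half_up(cns.eta_of * cbar), 1)
        cp_min = round_half_up(cns.eta_cmin * cbar)
        cp_max = round_half_up(cns.eta_cmax * cbar)
        wst = cand.index + offset
    if len(cps) < cns.K or not intervals:
        return None
    arr = np.asarray(intervals)
    if arr.std() / arr.mean() >= cns.init_max_cv:
        return None
    buf = tuple(arr[-cns.K:])
    cbar = float(np.mean(buf))
    omega, step, wst_new, cp_min, cp_max, delta = _derived(cbar, cps[-1], cns)
    state = WindowState(j=0, omega=omega, step=step, wst=wst_new, cbar=cbar,
                        intervals=buf, last_cp=cps[-1], cp_min=cp_min,
                        cp_max=cp_max, delta=delta)
    return state, cps


@dataclass
class SegmentationResult:
    """Everything a run produced: boundaries, the full cp chain, and the
    per-iteration window-state trajectory."""

    beats: list[BeatBoundaries]
    cps: np.ndarray                  # all detected cps incl. initialisation
    init_cps: np.ndarray
    init_intervals: tuple            # interval buffer as initialisation left it
    log: pd.DataFrame
    constants: WindowConstants
    fs: float


_LOG_COLS = ["wst", "omega", "step", "cbar", "P", "cand", "decision",
             "small_step", "interval"]


def segment_record(rec: EcgRecord, detector, cns: WindowConstants | None = None,
                   ) -> SegmentationResult:
    """Run the full loop over one record and emit per-beat boundaries.

    Needs no annotations.  Beats found during initialisation appear in
    ``cps`` but carry no boundaries; the method-II margins of each beat are
    filled in once the next critical point is confirmed, so the final beat
    keeps only method-I margins.
    """
    cns = cns or WindowConstants()
    signal = np.asarray(rec.signal, dtype=float)
    state, init_cps = initialize(signal, detector, cns, rec.fs)
    init_intervals = state.intervals
    cps: list[int] = list(init_cps)
    beats: list[BeatBoundaries] = []
    rows: list[tuple] = []
    n = signal.size
    while state.wst + state.omega <= n:
        lo, hi = state.wst, state.wst + state.omega
        window = signal[lo:hi]
        P = detector.predict_beat_proba(prepare(window, cns.M))
        if P < cns.p_b:
            rows.append((lo, state.omega, state.step, state.cbar, P, -1,
                         "advance", state.small_step, np.nan))
            state = update_on_miss(state, P, None, cns)
            continue
        cand = determine_cp(window, lo, cns.cp_rule)
        c = cand.index - state.last_cp
        if cand.degenerate or c < state.cp_min:
            rows.append((lo, state.omega, state.step, state.cbar, P,
                         cand.index, "too_close", state.small_step, c))
            state = update_on_miss(state, P, cand, cns)
            continue
        include = c <= state.cp_max
        decision = "accept" if include else "too_far"
        rows.append((lo, state.omega, state.step, state.cbar, P, cand.index,
                     decision, state.small_step, c))
        state, beat = update_on_detection(state, cand.index, cns,
                                          include_in_mean=include)
        beat = replace(beat, bl=max(beat.bl, 0), br=min(beat.br, n))
        if beats and len(cps) >= 2 and beats[-1].cp == cps[-1]:
            bl2, br2 = method2_boundaries(cps[-2], cps[-1], cand.index, cns)
            beats[-1] = replace(beats[-1], bl2=max(bl2, 0), br2=min(br2, n))
        cps.append(cand.index)
        beats.append(beat)
    log = pd.DataFrame(rows, columns=_LOG_COLS)
    return SegmentationResult(beats=beats, cps=np.asarray(cps, dtype=np.int64),
                              init_cps=np.asarray(init_cps, dtype=np.int64),
                              init_intervals=init_intervals, log=log,
                              constants=cns, fs=rec.fs)


class AdaptiveWindowSegmenter(BaseEstimator):
    """Parameter-carrying front end over :func:`segment_record`.

    The algorithm learns nothing from data, so ``fit`` only validates and
    freezes the constants; ``predict`` returns the detected critical
    points and ``segment`` the full result.
    """

    def __init__(self, detector=None, **constants):
        self.detector = detector
        for key, value in constants.items():
            setattr(self, key, value)
        self._constant_keys = tuple(constants)

    def get_params(self, deep=True):
        params = {"detector": self.detector}
        params.update({k: getattr(self, k) for k in self._constant_keys})
        return params

    def set_params(self, **params):
        for key, value in params.items():
            setattr(self, key, value)
            if key != "detector" and key not in self._constant_keys:
                self._constant_keys = self._constant_keys + (key,)
        return self

    def fit(self, X=None, y=None):
        if self.detector is None:
            raise ValueError("a detector is required")
        self.constants_ = WindowConstants(
            **{k: getattr(self, k) for k in self._constant_keys})
        return self

    def segment(self, rec: EcgRecord) -> SegmentationResult:
        if not hasattr(self, "constants_"):
            self.fit()
        return segment_record(rec, self.detector, self.constants_)

    def predict(self, rec: EcgRecord) -> np.ndarray:
        return self.segment(rec).cps
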