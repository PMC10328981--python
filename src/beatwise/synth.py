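"""Synthetic single-lead ECG with exact ground truth.

Each heartbeat is rendered as a sum of five Gaussians (P, Q, R, S, T), a
standard dynamical-model-style morphology, on an RR process with truncated
normal variability.  Optional ingredients emulate the failure modes the
segmentation algorithm must survive on real ambulatory recordings:
premature ectopic beats (early, wide, inverted QRS, followed by a
compensatory pause), additive white noise at a configurable SNR, and
sinusoidal baseline wander.  Ground truth is the exact R-wave centre of
every rendered beat, so detector and windowing behaviour can be scored
without any external database.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import AnnotatedBeat, EcgRecord
from .prep import DEFAULT_M, AlignedVector, prepare
from ._util import round_half_up


@dataclass(frozen=True)
class Wave:
    """One Gaussian wave: amplitude (mV), width sigma (s), offset from R (s)."""

    amp: float
    width: float
    offset: float


def default_morphology() -> dict[str, Wave]:
    return {
        "P": Wave(0.15, 0.035, -0.17),
        "Q": Wave(-0.10, 0.010, -0.026),
        "R": Wave(1.00, 0.012, 0.0),
        "S": Wave(-0.25, 0.010, 0.026),
        "T": Wave(0.35, 0.060, 0.30),
    }


def ectopic_morphology() -> dict[str, Wave]:
    """A PVC-like beat: no P wave, wide inverted QRS, discordant T."""
    return {
        "R": Wave(-0.90, 0.032, 0.0),
        "S": Wave(0.30, 0.020, 0.055),
        "T": Wave(0.45, 0.070, 0.32),
    }


@dataclass
class SynthConfig:
    fs: float = 360.0
    duration: float = 240.0
    mean_rr: float = 0.8
    rr_sd: float = 0.05
    morphology: dict[str, Wave] = field(default_factory=default_morphology)
    noise_snr: float | None = 20.0       # dB; None = noiseless
    baseline_amp: float = 0.3            # mV
    baseline_freq: float = 0.3           # Hz
    ectopic_rate: float = 0.0            # fraction of beats replaced by PVCs
    ectopic_morph: dict[str, Wave] = field(default_factory=ectopic_morphology)
    ectopic_early: float = 0.55          # ectopic RR as fraction of mean_rr
    ectopic_pause: float = 1.45          # compensatory pause fraction
    min_rr: float = 0.25                 # truncation floor (s)
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        if not 0 <= self.ectopic_rate < 1:
            raise ValueError("ectopic_rate must be in [0, 1)")
        widest = max(w.width for w in self.morphology.values())
        if self.mean_rr <= 3 * widest:
            raise ValueError("mean_rr too short for the configured wave widths")


@dataclass(frozen=True)
class SynthRecord:
    record: EcgRecord
    truth: list[AnnotatedBeat]


def _draw_beat_times(cfg: SynthConfig, rr_rng: np.random.Generator,
                     ect_rng: np.random.Generator):
    """Sequential RR process; ectopics are early insertions with a pause.

    Normal RR draws come from ``rr_rng`` and ectopic placement from
    ``ect_rng``, so two configs differing only in ``ectopic_rate`` share an
    identical underlying sinus rhythm — the ectopic run is the clean run
    with premature beats spliced in.
    """
    times: list[float] = []
    labels: list[str] = []
    limit = cfg.duration - 0.45 * cfg.mean_rr
    t = 0.45 * cfg.mean_rr
    while t < limit:
        times.append(t)
        labels.append("N")
        rr = max(rr_rng.normal(cfg.mean_rr, cfg.rr_sd), cfg.min_rr)
        if cfg.ectopic_rate > 0 and ect_rng.random() < cfg.ectopic_rate:
            # premature beat + compensatory pause replace this sinus interval
            t_e = t + cfg.ectopic_early * cfg.mean_rr
            if t_e >= limit:
                break
            times.append(t_e)
            labels.append("V")
            t = t_e + cfg.ectopic_pause * cfg.mean_rr
        else:
            t += rr
    return times, labels


def _render(times, labels, cfg: SynthConfig, n: int) -> np.ndarray:
    tax = np.arange(n) / cfg.fs
    sig = np.zeros(n)
    for t_c, lab in zip(times, labels):
        morph = cfg.ectopic_morph if lab == "V" else cfg.morphology
        lo = max(0, int((t_c - 0.5) * cfg.fs))
        hi = min(n, int((t_c + 0.6) * cfg.fs))
        seg = tax[lo:hi]
        for w in morph.values():
            sig[lo:hi] += w.amp * np.exp(-0.5 * ((seg - t_c - w.offset) / w.width) ** 2)
    return sig


def generate(cfg: SynthConfig) -> SynthRecord:
    """Render a record from the configured RR process, morphology and noise."""
    cfg.validate()
    streams = np.random.SeedSequence(cfg.seed).spawn(4)
    rr_rng, ect_rng, noise_rng, phase_rng = (np.random.default_rng(s) for s in streams)
    n = int(round(cfg.duration * cfg.fs))
    times, labels = _draw_beat_times(cfg, rr_rng, ect_rng)
    if not times:
        raise ValueError("configuration produces no beats")
    sig = _render(times, labels, cfg, n)
    if cfg.noise_snr is not None and math.isfinite(cfg.noise_snr):
        p_sig = float(np.var(sig))
        noise_sd = math.sqrt(p_sig / 10 ** (cfg.noise_snr / 10))
        sig = sig + noise_rng.normal(0.0, noise_sd, n)
    if cfg.baseline_amp > 0:
        phase = phase_rng.uniform(0, 2 * np.pi)
        sig = sig + cfg.baseline_amp * np.sin(
            2 * np.pi * cfg.baseline_freq * np.arange(n) / cfg.fs + phase)
    truth = [
        AnnotatedBeat(min(round_half_up(t * cfg.fs), n - 1), lab)
        for t, lab in zip(times, labels)
    ]
    rec = EcgRecord(record_id=f"synth{cfg.seed}", fs=cfg.fs, signal=sig,
                    native_fs=cfg.fs, annotations=truth)
    return SynthRecord(record=rec, truth=truth)


def make_template(cfg: SynthConfig | None = None, M: int = DEFAULT_M) -> AlignedVector:
    """One noiseless beat, symmetric about R, prepared for the oracle detector."""
    cfg = cfg or SynthConfig()
    half = round_half_up(0.4 * cfg.mean_rr * cfg.fs)
    fs = cfg.fs
    t_c = (half + 1) / fs
    n = 2 * half + 1
    sig = _render([t_c], ["N"], cfg, n + 2)[1:n + 1]
    return prepare(sig, M)
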