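"""Reference experiments on synthetic records.

These presets pin down the study conditions used to validate the package
end-to-end without any external database: a 300-beat noisy record for
detection accuracy, a paired clean/ectopic run for the interval-rejection
logic, and a reduced-scale CNN training run.  Both the test suite and the
reproduction script call these, so the reported numbers always come from
the same procedures.
"""

from __future__ import annotations

import math

import numpy as np

from .augment import build_dataset
from .detector import BeatSegmentCNN, oracle_detector
from .evaluation import match
from .synth import SynthConfig, generate, make_template
from .windowing import WindowConstants, segment_record

#: Conditions of the standard detection record: 240 s at 360 Hz (about
#: 300 beats at a 0.8 s mean RR), 20 dB SNR, 0.3 mV / 0.3 Hz baseline wander.
STANDARD_CONDITIONS = dict(fs=360.0, duration=240.0, mean_rr=0.8, rr_sd=0.05,
                           noise_snr=20.0, baseline_amp=0.3, baseline_freq=0.3)


def detection_experiment(seed: int = 1, tol_ms: float = 50.0,
                         constants: WindowConstants | None = None) -> dict:
    """Oracle-driven segmentation of the standard record, scored at ±50 ms."""
    cfg = SynthConfig(seed=seed, **STANDARD_CONDITIONS)
    sr = generate(cfg)
    det = oracle_detector(make_template(cfg))
    res = segment_record(sr.record, det, constants)
    truth = sr.record.annotation_indices()
    tp, fp, fn, _ = match(res.cps, truth, tol_ms, cfg.fs)
    se = 100.0 * tp / len(truth)
    pp = 100.0 * tp / max(tp + fp, 1)
    return {"n_true": int(len(truth)), "n_detected": int(res.cps.size),
            "tp": tp, "fp": fp, "fn": fn, "sensitivity_pct": se,
            "precision_pct": pp,
            "f1_pct": 2 * se * pp / (se + pp) if se + pp else 0.0,
            "result": res, "record": sr}


def _sinus_ordinal_trajectory(res, truth, fs: float) -> dict[int, float]:
    """Map accepted detections to sinus-beat ordinals with their C̄."""
    normals = np.array([a.sample_index for a in truth if a.label == "N"])
    acc = res.log[res.log.decision == "accept"]
    out: dict[int, float] = {}
    for cand, cbar in zip(acc["cand"], acc["cbar"]):
        i = int(np.argmin(np.abs(normals - cand)))
        if abs(int(normals[i]) - cand) <= 0.05 * fs:
            out[i] = float(cbar)
    return out


def ectopic_experiment(seed: int = 3, ectopic_rate: float = 0.05,
                       constants: WindowConstants | None = None) -> dict:
    """Paired clean/ectopic runs sharing one sinus rhythm.

    Reports how far the mean cp interval trajectory of the ectopic run
    strays from the clean run at matching sinus beats — small deviation
    means premature beats and compensatory pauses were kept out of the
    moving mean.
    """
    clean_cfg = SynthConfig(seed=seed, **STANDARD_CONDITIONS)
    ect_cfg = SynthConfig(seed=seed, ectopic_rate=ectopic_rate,
                          **STANDARD_CONDITIONS)
    det = oracle_detector(make_template(clean_cfg))
    clean = generate(clean_cfg)
    ect = generate(ect_cfg)
    res_c = segment_record(clean.record, det, constants)
    res_e = segment_record(ect.record, det, constants)
    tc = _sinus_ordinal_trajectory(res_c, clean.truth, clean_cfg.fs)
    te = _sinus_ordinal_trajectory(res_e, ect.truth, ect_cfg.fs)
    common = sorted(set(tc) & set(te))
    dev = np.array([abs(te[k] - tc[k]) / tc[k] for k in common])
    n_ect = sum(1 for a in ect.truth if a.label == "V")
    return {"n_common": len(common), "n_ectopic": n_ect,
            "max_deviation_pct": 100.0 * float(dev.max()),
            "mean_deviation_pct": 100.0 * float(dev.mean()),
            "clean": res_c, "ectopic": res_e}


def cnn_experiment(seed: int = 0, epochs: int = 3, n_train: int = 4,
                   n_test: int = 2, duration: float = 170.0) -> dict:
    """Reduced-scale training: ~20k augmented segments from ``n_train``
    synthetic records, scored on segments from held-out records."""
    conds = {**STANDARD_CONDITIONS, "duration": duration}
    train = [generate(SynthConfig(seed=seed * 1000 + s, **conds)).record
             for s in range(n_train)]
    test = [generate(SynthConfig(seed=seed * 1000 + 500 + s, **conds)).record
            for s in range(n_test)]
    ds_tr = build_dataset(train, folds=2)
    ds_te = build_dataset(test, folds=2)
    model = BeatSegmentCNN(epochs=epochs, random_state=seed)
    model.fit(ds_tr.X, ds_tr.y)
    pred = model.predict(ds_te.X)
    y = ds_te.y
    acc = float((pred == y).mean())
    se = float(pred[y == 1].mean()) if (y == 1).any() else math.nan
    sp = float((1 - pred[y == 0]).mean()) if (y == 0).any() else math.nan
    return {"n_train_examples": len(ds_tr), "n_test_examples": len(ds_te),
            "accuracy_pct": 100 * acc, "sensitivity_pct": 100 * se,
            "specificity_pct": 100 * sp, "model": model}


def alignment_bruteforce_mismatches(M: int = 512) -> int:
    """Compare the vectorised centring against a literal per-sample
    evaluation of the piecewise padding rule, for every source length."""
    from .prep import align

    mismatches = 0
    for L in range(1, M + 1):
        v = np.sin(np.arange(L) * 0.37) + np.arange(L) * 0.01
        w = align(v, M)
        lead = math.ceil((M - L) / 2)
        ref = np.empty(M)
        for n in range(M):
            if n < lead:
                ref[n] = v[0]
            elif n >= lead + L:
                ref[n] = v[L - 1]
            else:
                ref[n] = v[n - lead]
        mismatches += int(not np.array_equal(w, ref))
    return mismatches


def replay_geometry(res, constants: WindowConstants | None = None) -> dict:
    """Re-derive C̄ and the method-I geometry from the logged trajectory.

    Returns the worst disagreement between the logged mean and a
    brute-force mean over the accepted intervals, and the worst method-I
    length error against ``round(η_δ·C̄)``.
    """
    from ._util import round_half_up

    cns = constants or res.constants
    cbar0 = res.log["cbar"].iloc[0] if len(res.log) else None
    # the buffer starts as the initialisation left it; every later step is
    # recomputed from the logged decisions alone
    buf: list[float] = list(res.init_intervals)[-cns.K:]
    max_mean_err = 0.0
    max_len_err = 0
    max_ratio_err = 0.0
    beat_iter = iter(res.beats)
    for _, row in res.log.iterrows():
        expect = float(np.mean(buf[-cns.K:]))
        max_mean_err = max(max_mean_err, abs(expect - row["cbar"]))
        if row["decision"] in ("accept", "too_far"):
            if row["decision"] == "accept":
                buf.append(float(row["interval"]))
                buf = buf[-cns.K:]
            cbar_after = float(np.mean(buf[-cns.K:]))
            beat = next(beat_iter)
            length = beat.br - beat.bl
            # clipping at record edges may shorten a boundary legitimately
            if beat.bl > 0 and beat.br < res.cps[-1] + cns.M:
                max_len_err = max(
                    max_len_err,
                    abs(length - round_half_up(cns.eta_delta * cbar_after)))
                left, right = beat.cp - beat.bl, beat.br - beat.cp
                max_ratio_err = max(
                    max_ratio_err,
                    abs(left / right - cns.eta_ar / (1 - cns.eta_ar)) * right)
    return {"max_mean_error": max_mean_err, "max_length_error": max_len_err,
            "max_split_error_samples": max_ratio_err, "initial_cbar": cbar0}
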