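"""Validation studies on simulated sessions with known ground truth.

These routines quantify, over suites of seeded synthetic titration
sessions, how well each pipeline stage recovers the planted truth:
frame-level inspiration labelling (F1), interval overlap (IoU), and
end-to-end recovery of the planted adequate NAVA level.
"""

from __future__ import annotations

import numpy as np

from . import breath_detection as bd
from .io_signals import AlgorithmConfig
from .pipeline import analyze_recording
from .synthetic_data import (
    FIXTURE_TRANSITION_GRID,
    GroundTruth,
    generate_session,
    session_params_for,
)


def frame_label_truth(truth: GroundTruth, n_frames: int, nw: int) -> np.ndarray:
    """Per-frame inspiration truth: majority overlap with a planted burst."""
    mask = np.zeros(n_frames * nw, dtype=bool)
    for s, e in truth.neural_intervals:
        mask[s: min(e, mask.size)] = True
    return mask.reshape(n_frames, nw).mean(axis=1) >= 0.5


def interval_iou(truth_ivs, detected_ivs) -> np.ndarray:
    """Best intersection-over-union of each truth interval with any detection."""
    out = np.zeros(len(truth_ivs))
    for k, (s, e) in enumerate(truth_ivs):
        best = 0.0
        for ds, de in detected_ivs:
            inter = min(e, de) - max(s, ds)
            if inter > 0:
                best = max(best, inter / (max(e, de) - min(s, ds)))
        out[k] = best
    return out


def breath_detection_study(
    n_sessions: int = 25, seed: int = 1, cfg: AlgorithmConfig | None = None
) -> dict:
    """Frame-label F1 and interval IoU over seeded synthetic sessions."""
    cfg = cfg or AlgorithmConfig()
    f1s, ious, count_errs = [], [], []
    for i in range(n_sessions):
        params = session_params_for(seed, i)
        rec, truth = generate_session(params)
        smoothed = bd.lowpass_ma(rec.eadi, cfg.ma_order)
        frames = bd.frame_features(smoothed, cfg.frame_len, cfg.energy_floor)
        labels, _ = bd.classify_frames(frames, cfg)
        pred = labels == bd.LABEL_INSPIRATION
        truth_frames = frame_label_truth(truth, len(labels), cfg.frame_len)
        tp = int(np.sum(pred & truth_frames))
        fp = int(np.sum(pred & ~truth_frames))
        fn = int(np.sum(~pred & truth_frames))
        f1s.append(2 * tp / (2 * tp + fp + fn))
        detected = bd.extract_inspirations(labels, cfg.frame_len)
        ious.append(float(np.median(interval_iou(
            truth.neural_intervals, [(d.s, d.e) for d in detected]))))
        n_true = len(truth.neural_intervals)
        count_errs.append(abs(len(detected) - n_true) / n_true)
    return {
        "n_sessions": n_sessions,
        "f1_median": float(np.median(f1s)),
        "f1_per_session": f1s,
        "iou_median": float(np.median(ious)),
        "iou_per_session": ious,
        "breath_count_rel_err_max": float(np.max(count_errs)),
    }


def recovery_study(
    n_sessions: int = 50, seed: int = 1, cfg: AlgorithmConfig | None = None
) -> dict:
    """End-to-end recovery of the planted adequate level over a suite."""
    cfg = cfg or AlgorithmConfig()
    estimates, truths = [], []
    for i in range(n_sessions):
        params = session_params_for(seed, i)
        rec, truth = generate_session(params)
        report = analyze_recording(rec, cfg)
        estimates.append(report.nava_al)
        truths.append(truth.true_nava_al)
    estimates = np.array(estimates)
    truths = np.array(truths)
    errors = estimates - truths
    per_level = {
        level: float(np.median(estimates[truths == level]))
        for level in FIXTURE_TRANSITION_GRID if np.any(truths == level)
    }
    medians = [per_level[k] for k in sorted(per_level)]
    return {
        "n_sessions": n_sessions,
        "estimates": estimates.tolist(),
        "truths": truths.tolist(),
        "recovery_rate": float(np.mean(np.abs(errors) <= 0.5)),
        "median_abs_error": float(np.median(np.abs(errors))),
        "median_error": float(np.median(errors)),
        "per_level_median": per_level,
        "medians_strictly_increasing": bool(
            all(a < b for a, b in zip(medians, medians[1:]))),
    }
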