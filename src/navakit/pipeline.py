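"""End-to-end identification pipeline and its JSON-serializable report."""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np

from . import breath_detection as bd
from . import plateau_poly as pp
from .decision import DecisionResult, decide_nava_al
from .io_signals import AlgorithmConfig, TitrationRecording, read_recording
from .titration_tracking import TitrationWindow, find_titration_window

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class AnalysisReport:
    """Everything one pipeline run produced, ready for JSON serialization.

    Sample indices are 0-based; intervals are half-open ``[s, e)``.
    """

    schema_version: int
    input_path: str | None
    input_sha256: str | None
    config: dict
    fs: float
    n_samples: int
    window: dict
    n_neural_breaths: int
    n_flow_breaths: int
    paw_series: dict
    vt_series: dict
    paw_poly: dict
    vt_poly: dict
    n_hat_star: int
    nava_al: float
    decision_curve: dict
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _consistent_run(candidates: np.ndarray, ref: np.ndarray, y_max: float) -> int:
    """How many leading candidate values stay consistent with the reference.

    Consistency is |y - median(ref)| <= 6 robust SDs of ref (MAD-based, with
    a small floor so a noiseless reference does not reject everything).
    """
    med = float(np.median(ref))
    scale = 1.4826 * float(np.median(np.abs(ref - med)))
    scale = max(scale, 0.01 * y_max)
    ok = np.abs(candidates - med) <= 6.0 * scale
    bad = np.nonzero(~ok)[0]
    return int(bad[0]) if bad.size else candidates.size


def _clip_series(
    series: pp.BreathSeries, window: TitrationWindow, pad: int, n_ref: int = 25
) -> pp.BreathSeries:
    """Restrict a breath series to the titration window plus context breaths.

    High-degree polynomial fits are least trustworthy at the edges of their
    domain, so up to ``pad`` context breaths are kept on each side of the
    window, moving the untrustworthy edge region away from the decision
    window.  A context breath is only usable while the ventilator still
    operates near the window-edge condition, so padding stops at the first
    breath whose value is inconsistent (beyond 6 robust SDs) with the
    adjacent in-window breaths — e.g. breaths recorded at a much higher
    pre-titration assist level.
    """
    inside = np.nonzero((series.x >= window.n_ts) & (series.x < window.n_te))[0]
    if inside.size == 0:
        return series
    y_max = float(np.max(np.abs(series.y))) or 1.0
    first, last = int(inside[0]), int(inside[-1])
    ref_left = series.y[first: first + n_ref]
    left_candidates = series.y[:first][::-1]
    lo = first - min(pad, _consistent_run(left_candidates, ref_left, y_max))
    ref_right = series.y[max(last + 1 - n_ref, 0): last + 1]
    right_candidates = series.y[last + 1:]
    hi = last + 1 + min(pad, _consistent_run(right_candidates, ref_right, y_max))
    if hi - lo == len(series):
        return series
    return pp.BreathSeries(x=series.x[lo:hi], y=series.y[lo:hi], kind=series.kind)


def _poly_dict(model: pp.PlateauPolyModel) -> dict:
    return {
        "kind": model.kind,
        "order": model.order,
        "value_coeffs": list(model.value_coeffs),
        "err_coeffs": list(model.err_coeffs),
        "domain": list(model.domain),
        "y_scale": model.y_scale,
    }


def analyze_recording(
    rec: TitrationRecording,
    cfg: AlgorithmConfig | None = None,
    input_path: str | None = None,
    input_sha256: str | None = None,
) -> AnalysisReport:
    """Run the four-step identification on a recording.

    Step 1 locates the titration window on the NAVA-level staircase; step 2
    finds neural inspirations from the EAdi envelope; step 3 fits the
    robust plateau model to the airway-pressure peaks; step 4 does the same
    for tidal volumes and minimizes the fuzzy-weighted decision curve.
    """
    cfg = cfg or AlgorithmConfig()
    warnings: list[str] = []

    window, _labels = find_titration_window(rec.nava_level, cfg)

    smoothed = bd.lowpass_ma(rec.eadi, cfg.ma_order)
    frames = bd.frame_features(smoothed, cfg.frame_len, cfg.energy_floor)
    labels, _gmm = bd.classify_frames(frames, cfg)
    inspirations = bd.extract_inspirations(labels, cfg.frame_len)
    peak_idx, peak_val = bd.paw_peaks(rec, inspirations)
    paw_series = pp.BreathSeries(x=peak_idx, y=peak_val, kind="paw")

    flow_iv = pp.flow_inspirations(rec.flow, rec.fs, cfg.min_flow_insp_dur)
    vt_series = pp.tidal_volumes(rec.flow, flow_iv, rec.fs)

    # The plateau models describe the titration session located in step 1:
    # breaths outside the window (pre-titration context, post-titration
    # settling) are not part of the staircase response and would distort a
    # global polynomial, so they are excluded before fitting.
    # Pad by roughly one ripple half-wavelength of the order-K fit (N/K
    # breaths) so the whole decision window sits clear of the edge region.
    n_in = int(np.sum((paw_series.x >= window.n_ts) & (paw_series.x < window.n_te)))
    pad = max(cfg.poly_order, int(np.ceil(n_in / cfg.poly_order)))
    paw_fit = _clip_series(paw_series, window, pad=pad)
    vt_fit = _clip_series(vt_series, window, pad=pad)
    paw_model = pp.build_plateau_model(paw_fit, cfg)
    vt_model = pp.build_plateau_model(vt_fit, cfg)
    result: DecisionResult = decide_nava_al(
        pp.info_function(paw_model),
        pp.info_function(vt_model),
        window,
        rec.nava_level,
        cfg,
    )
    if result.samples[0] > window.n_ts or result.samples[-1] < window.n_te - 1:
        warnings.append(
            "decision curve evaluated on the part of the window covered by breaths"
        )

    curve = result.curve
    return AnalysisReport(
        schema_version=REPORT_SCHEMA_VERSION,
        input_path=input_path,
        input_sha256=input_sha256,
        config=cfg.to_dict(),
        fs=rec.fs,
        n_samples=rec.n_samples,
        window={"n_ts": window.n_ts, "n_te": window.n_te, "n_td": window.n_td},
        n_neural_breaths=len(inspirations),
        n_flow_breaths=len(flow_iv),
        paw_series={"x": [int(v) for v in paw_series.x], "y": list(paw_series.y)},
        vt_series={"x": [int(v) for v in vt_series.x], "y": list(vt_series.y)},
        paw_poly=_poly_dict(paw_model),
        vt_poly=_poly_dict(vt_model),
        n_hat_star=result.n_hat_star,
        nava_al=result.nava_al,
        decision_curve={
            "first_sample": int(result.samples[0]),
            "last_sample": int(result.samples[-1]),
            "min": float(curve.min()),
            "max": float(curve.max()),
        },
        warnings=warnings,
    )


def analyze_file(
    path, cfg: AlgorithmConfig | None = None, fs_override: float | None = None
) -> AnalysisReport:
    """Read a recording CSV and run the full identification on it."""
    with open(path, "rb") as fh:
        digest = hashlib.sha256(fh.read()).hexdigest()
    rec = read_recording(path, fs_override=fs_override)
    return analyze_recording(rec, cfg, input_path=str(path), input_sha256=digest)
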