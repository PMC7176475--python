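"""Locating the titration session in the NAVA-level trace.

The NAVA level during a titration session is a noiseless staircase: the
clinician raises the assist gain by a fixed increment (0.1 cmH2O/µV) every
20 s.  The trace is first compressed losslessly into maximal exact line
segments; each segment is then described by two features — the log absolute
offset jump from the previous segment and the log segment length — which are
nearly constant across staircase steps and scattered elsewhere.  A
2-component Gaussian mixture is fitted to the feature cloud, the component
with the smaller covariance determinant is taken as the Titration class, and
the titration window runs from the earliest start to the latest end of the
segments assigned to that class by the Bayes rule.

All indices are 0-based and all intervals half-open ``[s, e)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import multivariate_normal
from sklearn.mixture import GaussianMixture

from .errors import NoTitrationFound, NumericalError, ValidationError
from .io_signals import AlgorithmConfig

logger = logging.getLogger(__name__)

_EXTEND_CHUNK = 256  # samples checked per vectorized extension step


@dataclass(frozen=True)
class LineSegment:
    """One maximal exact line ``signal[n] = a*n + b`` over ``[s, e)``."""

    a: float
    b: float
    s: int
    e: int

    @property
    def length(self) -> int:
        return self.e - self.s

    def evaluate(self, n) -> np.ndarray:
        return self.a * np.asarray(n, dtype=float) + self.b


@dataclass(frozen=True)
class SegmentFeatures:
    """Classification features of one line segment (both log-domain)."""

    log_offset_jump: float
    log_length: float

    def as_array(self) -> np.ndarray:
        return np.array([self.log_offset_jump, self.log_length])


@dataclass(frozen=True)
class GmmModel:
    """A fitted Gaussian mixture (full covariances)."""

    n_components: int
    means: np.ndarray        # (k, d)
    covariances: np.ndarray  # (k, d, d)
    weights: np.ndarray      # (k,)
    degenerate: bool = False

    def component_pdf(self, x: np.ndarray, j: int) -> np.ndarray:
        """Density of component j at points x, without the mixing weight."""
        return multivariate_normal.pdf(
            x, mean=self.means[j], cov=self.covariances[j], allow_singular=True
        )

    def covariance_determinants(self) -> np.ndarray:
        return np.array([np.linalg.det(c) for c in self.covariances])


@dataclass(frozen=True)
class TitrationWindow:
    """Detected titration interval ``[n_ts, n_te)`` in samples."""

    n_ts: int
    n_te: int

    def __post_init__(self):
        if not self.n_ts < self.n_te:
            raise ValidationError("titration window requires n_ts < n_te")

    @property
    def n_td(self) -> int:
        """Window duration in samples."""
        return self.n_te - self.n_ts


def segment_lines(signal, tol: float) -> list[LineSegment]:
    """Greedily split a signal into maximal exactly-linear runs.

    A line is anchored on two consecutive samples and extended while the next
    sample lies on it within ``tol`` (absolute).  On a violation a new line
    starts from the next two samples.  The returned segments partition
    ``[0, n)`` in order, and piecewise evaluation reproduces the input
    within ``tol``.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("segment_lines needs a 1-D signal of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValidationError("segment_lines requires finite values")
    n = x.size
    segments: list[LineSegment] = []
    s = 0
    while s < n:
        if s == n - 1:
            # trailing orphan sample: degenerate flat segment
            segments.append(LineSegment(0.0, float(x[s]), s, n))
            break
        a = float(x[s + 1] - x[s])
        b = float(x[s]) - a * s
        e = s + 2
        while e < n:
            stop = min(e + _EXTEND_CHUNK, n)
            idx = np.arange(e, stop)
            dev = np.abs(x[e:stop] - (a * idx + b))
            viol = np.nonzero(dev > tol)[0]
            if viol.size:
                e += int(viol[0])
                break
            e = stop
        segments.append(LineSegment(a, b, s, e))
        s = e
    return segments


def segment_features(
    segments: list[LineSegment], floor: float = math.log(1e-12)
) -> list[SegmentFeatures]:
    """Feature vectors for segments 1..L-1 (the first has no predecessor).

    Both the absolute offset jump and the length are floored at
    ``exp(floor)`` before taking logs so the features stay finite even for
    repeated offsets.
    """
    if len(segments) < 2:
        raise ValidationError("need at least 2 segments to build features")
    lin_floor = math.exp(floor)
    feats = []
    for prev, cur in zip(segments[:-1], segments[1:]):
        jump = max(abs(cur.b - prev.b), lin_floor)
        length = max(cur.length, lin_floor)
        feats.append(SegmentFeatures(math.log(jump), math.log(length)))
    return feats


def fit_gmm(points, n_components: int, cfg: AlgorithmConfig | None = None) -> GmmModel:
    """Maximum-likelihood Gaussian mixture via EM (full covariances).

    Deterministic for a fixed ``cfg.gmm_seed``; k-means++ initialization
    with ``cfg.gmm_restarts`` restarts and a ridge ``cfg.gmm_reg_covar`` on
    the covariance diagonals.  A mixture whose smallest covariance
    determinant collapses to the ridge scale is flagged degenerate.
    """
    cfg = cfg or AlgorithmConfig()
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(np.isfinite(pts)):
        raise ValidationError("fit_gmm requires finite features")
    if pts.shape[0] <= n_components:
        raise ValidationError(
            f"need more than {n_components} points, got {pts.shape[0]}"
        )
    gm = GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        reg_covar=cfg.gmm_reg_covar,
        n_init=cfg.gmm_restarts,
        init_params="k-means++",
        random_state=cfg.gmm_seed,
        max_iter=200,
    )
    try:
        gm.fit(pts)
    except ValueError as exc:  # pragma: no cover - sklearn internal failure
        raise NumericalError(f"EM failed: {exc}") from exc
    dets = np.array([np.linalg.det(c) for c in gm.covariances_])
    dim = pts.shape[1]
    degenerate = bool(np.any(dets <= (4.0 * cfg.gmm_reg_covar) ** dim))
    return GmmModel(
        n_components=n_components,
        means=gm.means_.copy(),
        covariances=gm.covariances_.copy(),
        weights=gm.weights_.copy(),
        degenerate=degenerate,
    )


def classify_segments(
    feats: list[SegmentFeatures], cfg: AlgorithmConfig | None = None
) -> tuple[np.ndarray, GmmModel, int]:
    """Assign each featured segment to Titration (True) or Non-titration.

    Returns per-feature boolean labels, the fitted 2-component mixture, and
    the index of the titration component (the one with the smaller
    covariance determinant).  Assignment is the Bayes rule on the plain
    component densities.
    """
    X = np.array([f.as_array() for f in feats])
    gmm = fit_gmm(X, 2, cfg)
    titration_comp = int(np.argmin(gmm.covariance_determinants()))
    dens = np.column_stack([gmm.component_pdf(X, j) for j in range(2)])
    assigned = np.argmax(dens, axis=1)
    return assigned == titration_comp, gmm, titration_comp


def find_titration_window(
    signal, cfg: AlgorithmConfig | None = None
) -> tuple[TitrationWindow, np.ndarray]:
    """Detect the titration window in a NAVA-level trace.

    Returns the window and per-segment boolean titration labels (index
    aligned with ``segment_lines`` output; the first segment inherits the
    label of the second).  Raises :class:`NoTitrationFound` when the trace
    has fewer than 4 line segments or no segment lands in the titration
    class.
    """
    cfg = cfg or AlgorithmConfig()
    segments = segment_lines(signal, cfg.line_tol)
    if len(segments) < 4:
        raise NoTitrationFound(
            f"only {len(segments)} line segments: no staircase structure"
        )
    feats = segment_features(segments, cfg.feature_floor)
    feat_labels, _, _ = classify_segments(feats, cfg)
    labels = np.empty(len(segments), dtype=bool)
    labels[1:] = feat_labels
    labels[0] = labels[1]
    if not labels.any():
        raise NoTitrationFound("no segment assigned to the titration class")
    tit = [seg for seg, lab in zip(segments, labels) if lab]
    n_ts = min(seg.s for seg in tit)
    n_te = max(seg.e for seg in tit)
    inside = [seg for seg in segments if seg.s >= n_ts and seg.e <= n_te]
    gaps = sum(1 for seg, lab in zip(segments, labels) if not lab and seg in inside)
    if gaps:
        logger.warning(
            "titration window contains %d interior non-titration segment(s)", gaps
        )
    return TitrationWindow(n_ts, n_te), labels
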