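"""Robust polynomial plateau models for breath-indexed series.

The transition to adequate assist shows up as a plateau in two per-breath
series: the airway-pressure peaks and the tidal volumes (the integral of
positive flow over each flow inspiration).  Each series is summarized by a
degree-K polynomial fitted with iteratively reweighted least squares (Tukey
bisquare by default) so that false-trigger breaths with near-zero volume do
not drag the fit, plus a degree-(K-1) polynomial fitted to the square root
of the absolute fit residuals.  The squared slope of the value polynomial
plus the squared error polynomial form an information function that is
small exactly where the series is flat *and* regular — the signature of the
plateau.

Fitting a degree-10 polynomial on raw sample indices (~1e5) is numerically
singular, so the predictor is mapped to t in [0, 1] over the span of the
series and the response is scaled by its maximum absolute value before
fitting; the information function is evaluated in that normalized domain,
which also makes the pressure and volume terms dimensionless and
commensurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .breath_detection import BreathInterval
from .errors import DomainError, NumericalError, ValidationError
from .io_signals import AlgorithmConfig

_MAD_TO_SIGMA = 0.6745  # MAD of a normal sample estimates 0.6745*sigma


@dataclass(frozen=True)
class BreathSeries:
    """A per-breath series: sample index of each breath and its value."""

    x: np.ndarray   # sample indices, strictly increasing
    y: np.ndarray   # cmH2O (paw) or litres (vt)
    kind: str       # "paw" | "vt"

    def __post_init__(self):
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.kind not in ("paw", "vt"):
            raise ValidationError(f"unknown series kind {self.kind!r}")
        if self.x.size != self.y.size:
            raise ValidationError("x and y must have equal length")
        if self.x.size and np.any(np.diff(self.x) <= 0):
            raise ValidationError("breath sample indices must be strictly increasing")

    def __len__(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class PlateauPolyModel:
    """Value + error polynomials of one breath series (normalized domain)."""

    kind: str
    order: int
    value_coeffs: np.ndarray   # K+1 coefficients, increasing powers of t
    err_coeffs: np.ndarray     # K coefficients, increasing powers of t
    domain: tuple[float, float]  # sample-index span mapped onto t in [0, 1]
    y_scale: float

    def to_t(self, n) -> np.ndarray:
        lo, hi = self.domain
        return (np.asarray(n, dtype=float) - lo) / (hi - lo)

    def value(self, n) -> np.ndarray:
        """Fitted series value at sample index n, back on the data scale."""
        return np.polynomial.polynomial.polyval(self.to_t(n), self.value_coeffs) * self.y_scale


def flow_inspirations(flow, fs: float, min_dur: float = 0.16) -> list[BreathInterval]:
    """Flow inspirations: maximal runs of positive flow (zero crossings).

    Runs shorter than ``min_dur`` seconds are discarded as false-trigger
    artifacts.
    """
    f = np.asarray(flow, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValidationError("flow must be finite")
    pos = np.concatenate(([False], f > 0, [False]))
    d = np.diff(pos.astype(int))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    out = []
    b = 0
    for s, e in zip(starts, ends):
        if (e - s) / fs < min_dur:
            continue
        out.append(BreathInterval("flow", b, int(s), int(e)))
        b += 1
    return out


def tidal_volumes(flow, intervals: list[BreathInterval], fs: float) -> BreathSeries:
    """Tidal volume of each flow inspiration, in litres.

    Vt(b) = (1/fs) * sum of flow over the interval; the series is indexed by
    the interval start samples.
    """
    f = np.asarray(flow, dtype=float)
    x = np.array([iv.s for iv in intervals], dtype=float)
    y = np.array([f[iv.s: iv.e].sum() / fs for iv in intervals], dtype=float)
    return BreathSeries(x=x, y=y, kind="vt")


def _bisquare_weights(u: np.ndarray) -> np.ndarray:
    w = np.zeros_like(u)
    inside = np.abs(u) < 1.0
    w[inside] = (1.0 - u[inside] ** 2) ** 2
    return w


def _huber_weights(u: np.ndarray) -> np.ndarray:
    au = np.abs(u)
    w = np.ones_like(u)
    big = au > 1.0
    w[big] = 1.0 / au[big]
    return w


def fit_rwls_poly(
    x, y, order: int, cfg: AlgorithmConfig | None = None
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Robust polynomial fit by iteratively reweighted least squares.

    The predictor is mapped internally onto t in [0, 1] over its span.
    Residuals are scaled by the normalized MAD; weights are Tukey bisquare
    (tuning 4.685) or Huber per ``cfg.rwls_weight``; iteration stops when
    the weight vector moves less than ``cfg.rwls_tol`` in max-norm or after
    ``cfg.rwls_max_iter`` rounds.  On data that an order-``order``
    polynomial fits exactly the result coincides with ordinary least
    squares.

    Returns (coefficients in increasing powers of t, final weights,
    (lo, hi) domain of the t-mapping).
    """
    cfg = cfg or AlgorithmConfig()
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size:
        raise ValidationError("x and y must have equal length")
    if xv.size < order + 2:
        raise ValidationError(f"need at least {order + 2} points for order {order}")
    if np.unique(xv).size != xv.size:
        raise ValidationError("x values must be distinct")
    lo, hi = float(xv.min()), float(xv.max())
    t = (xv - lo) / (hi - lo)
    V = np.vander(t, order + 1, increasing=True)
    if np.linalg.matrix_rank(V) < order + 1:
        raise NumericalError("design matrix is rank deficient")
    weight_fn = _bisquare_weights if cfg.rwls_weight == "bisquare" else _huber_weights
    c = cfg.rwls_tuning if cfg.rwls_weight == "bisquare" else 1.345
    beta, *_ = np.linalg.lstsq(V, yv, rcond=None)
    w = np.ones_like(yv)
    for _ in range(cfg.rwls_max_iter):
        r = yv - V @ beta
        mad = np.median(np.abs(r - np.median(r)))
        scale = mad / _MAD_TO_SIGMA
        if scale < 1e-12 * max(1.0, np.max(np.abs(yv))):
            w = np.ones_like(yv)
            break  # essentially exact fit
        w_new = weight_fn(r / (c * scale))
        if not w_new.any():  # pathological: keep previous weights
            break
        sw = np.sqrt(w_new)
        beta, *_ = np.linalg.lstsq(V * sw[:, None], yv * sw, rcond=None)
        if np.max(np.abs(w_new - w)) < cfg.rwls_tol:
            w = w_new
            break
        w = w_new
    return beta, w, (lo, hi)


def build_plateau_model(
    series: BreathSeries, cfg: AlgorithmConfig | None = None
) -> PlateauPolyModel:
    """Fit the value and error polynomials of one breath series.

    The response is normalized by ``y_scale = max |y|``; the error series is
    sqrt(|fit - value|) of the normalized residuals, fitted at order K-1 by
    the same reweighting scheme.
    """
    cfg = cfg or AlgorithmConfig()
    K = cfg.poly_order
    if len(series) < K + 2:
        raise ValidationError(
            f"series of {len(series)} breaths is too short for order {K}"
        )
    y_scale = float(np.max(np.abs(series.y)))
    if y_scale == 0.0:
        y_scale = 1.0
    ys = series.y / y_scale
    value_coeffs, _, domain = fit_rwls_poly(series.x, ys, K, cfg)
    lo, hi = domain
    t = (series.x - lo) / (hi - lo)
    fitted = np.polynomial.polynomial.polyval(t, value_coeffs)
    eps = np.sqrt(np.abs(fitted - ys))
    err_coeffs, _, _ = fit_rwls_poly(series.x, eps, K - 1, cfg)
    return PlateauPolyModel(
        kind=series.kind,
        order=K,
        value_coeffs=value_coeffs,
        err_coeffs=err_coeffs,
        domain=domain,
        y_scale=y_scale,
    )


def info_function(model: PlateauPolyModel) -> Callable[[np.ndarray], np.ndarray]:
    """Plateau information function of a fitted model.

    Returns a callable over sample indices n evaluating
    ``[dH/dt(t(n))]^2 + [H_err(t(n))]^2`` in the normalized domain; it is
    nonnegative everywhere and raises :class:`DomainError` outside the span
    of the fitted series.
    """
    dcoeffs = np.polynomial.polynomial.polyder(model.value_coeffs)
    lo, hi = model.domain

    def info(n) -> np.ndarray:
        n_arr = np.asarray(n, dtype=float)
        if np.any(n_arr < lo) or np.any(n_arr > hi):
            raise DomainError(
                f"sample index outside fitted domain [{lo:g}, {hi:g}]"
            )
        t = (n_arr - lo) / (hi - lo)
        slope = np.polynomial.polynomial.polyval(t, dcoeffs)
        err = np.polynomial.polynomial.polyval(t, model.err_coeffs)
        return slope * slope + err * err

    info.domain = (lo, hi)  # type: ignore[attr-defined]
    return info
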