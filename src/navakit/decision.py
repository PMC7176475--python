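"""Final decision: where along the titration the plateau begins.

The airway-pressure and tidal-volume information functions are summed and
multiplied by a fuzzy-logic prior, a Gaussian-shaped factor in [0.5, 1.5)
whose minimum sits at the first quarter of the titration window — clinicians
overwhelmingly pick the adequate level early in the session, and with a
linear staircase that temporal bias maps directly onto the level axis.  The
adequate NAVA level is the recorded assist gain at the sample where the
resulting decision curve is minimal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ValidationError
from .io_signals import AlgorithmConfig
from .titration_tracking import TitrationWindow


@dataclass(frozen=True)
class DecisionResult:
    """Outcome of the decision stage."""

    n_hat_star: int           # sample index of the decision-curve minimum
    nava_al: float            # assist gain at that sample, cmH2O/µV
    curve: np.ndarray         # decision values over the evaluated samples
    samples: np.ndarray       # the samples the curve was evaluated on
    window: TitrationWindow


def fuzzy_factor(
    n, window: TitrationWindow, cfg: AlgorithmConfig | None = None
) -> np.ndarray:
    """Gaussian fuzzy prior: 1.5 minus the peak-normalized density.

    The density is centered at ``n_ts + n_td * fuzzy_mean_frac`` (default
    the first-quarter point) with spread ``n_td * fuzzy_spread_frac``
    interpreted as a standard deviation by default.  Values lie in
    [0.5, 1.5), equal 0.5 exactly at the center, and are symmetric about it.
    Raises :class:`DomainError` for samples outside ``[n_ts, n_te)``.
    """
    cfg = cfg or AlgorithmConfig()
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr < window.n_ts) or np.any(n_arr >= window.n_te):
        raise DomainError("fuzzy factor is defined on the titration window only")
    mean = window.n_ts + window.n_td * cfg.fuzzy_mean_frac
    spread = window.n_td * cfg.fuzzy_spread_frac
    sd = spread if cfg.fuzzy_spread_is_sd else np.sqrt(spread)
    g = np.exp(-0.5 * ((n_arr - mean) / sd) ** 2)  # peak-normalized density
    return 1.5 - g


def decide_nava_al(
    paw_info,
    vt_info,
    window: TitrationWindow,
    nava_level,
    cfg: AlgorithmConfig | None = None,
) -> DecisionResult:
    """Minimize the fuzzy-weighted sum of the two information functions.

    The decision curve is evaluated densely on every sample of the
    titration window that lies inside both information-function domains
    (breath series need not span the entire window); ties at the minimum
    break to the earliest sample.  The adequate NAVA level is read off the
    recorded staircase at the minimizing sample, without interpolation.
    """
    cfg = cfg or AlgorithmConfig()
    level = np.asarray(nava_level, dtype=float)
    if window.n_te > level.size:
        raise ValidationError("titration window extends past the recording")
    lo = float(window.n_ts)
    hi = float(window.n_te - 1)
    for info in (paw_info, vt_info):
        dom = getattr(info, "domain", None)
        if dom is not None:
            lo = max(lo, dom[0])
            hi = min(hi, dom[1])
    if hi < lo:
        raise DomainError(
            "titration window lies outside the fitted information domains"
        )
    samples = np.arange(int(np.ceil(lo)), int(np.floor(hi)) + 1)
    curve = (paw_info(samples) + vt_info(samples)) * fuzzy_factor(
        samples, window, cfg
    )
    if not np.all(np.isfinite(curve)):
        raise ValidationError("decision curve contains non-finite values")
    n_hat = int(samples[int(np.argmin(curve))])  # argmin: earliest on ties
    return DecisionResult(
        n_hat_star=n_hat,
        nava_al=float(level[n_hat]),
        curve=curve,
        samples=samples,
        window=window,
    )
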