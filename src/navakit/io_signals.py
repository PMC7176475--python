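"""Domain types and plain-text I/O for NAVA titration recordings.

A titration recording holds the synchronized channels of one NAVA-level
titration session: the assist gain (NAVA level, cmH2O/µV), the diaphragm
electrical activity (EAdi, µV) and the airway flow (L/s), all sampled on a
common uniform grid (62.5 Hz on the ventilator these sessions come from).
Recordings are exchanged as plain CSV with the header

    time_s,nava_level,eadi_uV,flow_L_s[,paw_cmH2O]

one row per sample, full double precision.  A measured airway-pressure
column is optional and carried for plotting only: the identification
algorithm always reconstructs Paw as NAVA_level * EAdi.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: Default sampling rate of the ventilator exports this package targets.
DEFAULT_FS = 62.5

REQUIRED_COLUMNS = ("nava_level", "eadi_uV", "flow_L_s")
OPTIONAL_COLUMNS = ("time_s", "paw_cmH2O")


def _as_channel(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"channel {name!r} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class TitrationRecording:
    """Synchronized waveforms of one titration session.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz, identical for all channels.
    nava_level : array of float
        Per-sample assist gain in cmH2O/µV; finite and nonnegative.
    eadi : array of float
        Per-sample diaphragm electrical activity in µV.
    flow : array of float
        Per-sample airway flow in L/s (inspiration positive).
    paw_measured : array of float, optional
        Measured airway pressure in cmH2O, carried for plotting only.
    """

    fs: float
    nava_level: np.ndarray
    eadi: np.ndarray
    flow: np.ndarray
    paw_measured: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "nava_level", _as_channel(self.nava_level, "nava_level"))
        object.__setattr__(self, "eadi", _as_channel(self.eadi, "eadi"))
        object.__setattr__(self, "flow", _as_channel(self.flow, "flow"))
        if self.paw_measured is not None:
            object.__setattr__(
                self, "paw_measured", _as_channel(self.paw_measured, "paw_measured")
            )
        n = self.nava_level.size
        if n < 2:
            raise ValidationError("a recording needs at least 2 samples")
        for name in ("eadi", "flow", "paw_measured"):
            ch = getattr(self, name)
            if ch is not None and ch.size != n:
                raise ValidationError(
                    f"channel {name!r} has {ch.size} samples, expected {n}"
                )
        if not (self.fs > 0 and math.isfinite(self.fs)):
            raise ValidationError(f"fs must be positive and finite, got {self.fs}")
        if not np.all(np.isfinite(self.nava_level)):
            raise ValidationError("nava_level must be finite everywhere")
        if np.any(self.nava_level < 0):
            raise ValidationError("nava_level must be nonnegative everywhere")

    @property
    def n_samples(self) -> int:
        return self.nava_level.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def time(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.fs

    def paw(self) -> np.ndarray:
        """Airway pressure reconstructed as NAVA_level * EAdi (cmH2O)."""
        return self.nava_level * self.eadi


@dataclass(frozen=True)
class AlgorithmConfig:
    """Tunable constants of the identification pipeline.

    The first three fields are the method's published constants; the rest is
    implementation plumbing (tolerances, robust-fit and EM settings) with
    conservative defaults.
    """

    ma_order: int = 40          # moving-average length, samples (~4 Hz cutoff at 62.5 Hz)
    frame_len: int = 15         # short-term energy frame, samples (240 ms at 62.5 Hz)
    poly_order: int = 10        # plateau polynomial order K
    energy_floor: float = 1e-12  # floor under frame energies before log
    line_tol: float = 1e-9      # absolute tolerance for the exact-line test
    min_flow_insp_dur: float = 0.16  # s; shorter positive-flow runs are artifacts
    feature_floor: float = math.log(1e-12)  # log-space floor for segment features
    rwls_weight: str = "bisquare"   # "bisquare" or "huber"
    rwls_tuning: float = 4.685      # Tukey bisquare tuning constant
    rwls_max_iter: int = 50
    rwls_tol: float = 1e-6          # convergence tolerance on the weight vector
    gmm_restarts: int = 10
    gmm_reg_covar: float = 1e-6
    gmm_seed: int = 0
    fuzzy_mean_frac: float = 0.25   # fuzzy prior mean as a fraction of window length
    fuzzy_spread_frac: float = 1.0 / 3.0  # fuzzy prior spread fraction
    fuzzy_spread_is_sd: bool = True  # interpret spread as an SD (else a variance)

    def __post_init__(self):
        if self.ma_order < 1 or self.frame_len < 1:
            raise ValidationError("ma_order and frame_len must be >= 1")
        if self.poly_order < 2:
            raise ValidationError("poly_order must be >= 2")
        for name in ("energy_floor", "line_tol", "min_flow_insp_dur",
                     "rwls_tuning", "rwls_tol", "gmm_reg_covar"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.rwls_weight not in ("bisquare", "huber"):
            raise ValidationError(f"unknown rwls weight {self.rwls_weight!r}")
        if self.rwls_max_iter < 1 or self.gmm_restarts < 1:
            raise ValidationError("iteration/restart counts must be >= 1")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _infer_fs(time_s: np.ndarray) -> float:
    dt = np.diff(time_s)
    if dt.size == 0 or np.any(dt <= 0):
        raise FormatError("time_s must be strictly increasing")
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > 0.01 * med:
        raise FormatError("time_s grid is non-uniform beyond 1%")
    # One rounding to 12 significant digits undoes the double rounding in
    # 1/median(diff(k/fs)) so that a grid written from fs recovers fs exactly.
    return float(f"{1.0 / med:.12g}")


def read_recording(path, fs_override: float | None = None) -> TitrationRecording:
    """Read a titration recording from a CSV file.

    The file must carry a header naming at least ``nava_level``, ``eadi_uV``
    and ``flow_L_s``; ``time_s`` and ``paw_cmH2O`` are optional.  The
    sampling rate is taken from ``fs_override`` when given, otherwise
    inferred from the ``time_s`` column, which must be uniform within 1%.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    for col in REQUIRED_COLUMNS:
        vals = df[col].to_numpy(dtype=float)
        bad = np.nonzero(~np.isfinite(vals))[0]
        if bad.size:
            raise ValidationError(
                f"channel {col!r} has a non-finite value at row {int(bad[0])}"
            )
    if fs_override is not None:
        fs = float(fs_override)
    elif "time_s" in df.columns:
        fs = _infer_fs(df["time_s"].to_numpy(dtype=float))
    else:
        raise FormatError("no time_s column: pass fs_override to set the rate")
    paw = df["paw_cmH2O"].to_numpy(dtype=float) if "paw_cmH2O" in df.columns else None
    return TitrationRecording(
        fs=fs,
        nava_level=df["nava_level"].to_numpy(dtype=float),
        eadi=df["eadi_uV"].to_numpy(dtype=float),
        flow=df["flow_L_s"].to_numpy(dtype=float),
        paw_measured=paw,
    )


def write_recording(rec: TitrationRecording, path) -> None:
    """Write a recording as CSV; round-trips exactly through read_recording."""
    cols = {
        "time_s": rec.time(),
        "nava_level": rec.nava_level,
        "eadi_uV": rec.eadi,
        "flow_L_s": rec.flow,
    }
    if rec.paw_measured is not None:
        cols["paw_cmH2O"] = rec.paw_measured
    with open(path, "w", newline="") as fh:
        fh.write(",".join(cols) + "\n")
        arrays = list(cols.values())
        for i in range(rec.n_samples):
            fh.write(",".join(repr(float(a[i])) for a in arrays) + "\n")
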