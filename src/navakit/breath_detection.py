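"""Neural inspiration detection from the diaphragm EMG envelope.

EAdi is smoothed with a causal moving average (order 40 ≈ 4 Hz cutoff at
62.5 Hz), cut into non-overlapping 15-sample frames (240 ms), and each frame
is described by its log short-term energy and the first difference thereof.
Breath cycles in intensive-care patients last roughly 1–4 s, so inspiratory
"mountains" and expiratory "valleys" of the envelope are several frames
long.  A 3-component Gaussian mixture is fitted to the feature cloud: the
component with the lowest mean energy is the Neural Expiration class, the
other two (rising and falling envelope slopes) jointly form the Neural
Inspiration class.  Maximal runs of inspiration frames become neural
inspiration intervals, inside which the airway-pressure peaks are read off
the reconstructed Paw = NAVA_level * EAdi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSignal, ValidationError
from .io_signals import AlgorithmConfig, TitrationRecording
from .titration_tracking import GmmModel, fit_gmm

LABEL_EXPIRATION = 0
LABEL_INSPIRATION = 1


@dataclass(frozen=True)
class FrameFeatures:
    """Log short-term energy features of one analysis frame."""

    frame_index: int
    end_sample: int   # exclusive end of the frame, in samples
    e: float          # log mean squared amplitude
    de: float         # first difference of e (0 for the first frame)


@dataclass(frozen=True)
class BreathInterval:
    """One inspiration interval ``[s, e)``, neural or flow-derived."""

    kind: str  # "neural" | "flow"
    b: int     # breath index, temporal order
    s: int
    e: int
    peak: int | None = None  # sample of maximal Paw (neural kind only)

    def __post_init__(self):
        if self.kind not in ("neural", "flow"):
            raise ValidationError(f"unknown breath kind {self.kind!r}")
        if not self.s < self.e:
            raise ValidationError("breath interval requires s < e")

    @property
    def length(self) -> int:
        return self.e - self.s


def lowpass_ma(eadi, order: int = 40) -> np.ndarray:
    """Causal moving average of the given order.

    The first ``order - 1`` output samples average the available prefix, so
    the output has the input's length and a nonnegative input yields a
    nonnegative output.
    """
    x = np.asarray(eadi, dtype=float)
    if order < 1:
        raise ValidationError("order must be >= 1")
    if x.size < order:
        raise ValidationError(f"signal ({x.size}) shorter than MA order ({order})")
    csum = np.concatenate(([0.0], np.cumsum(x)))
    out = np.empty_like(x)
    out[order - 1:] = (csum[order:] - csum[:-order]) / order
    head = np.arange(1, order)
    out[: order - 1] = csum[1:order] / head
    return out


def frame_features(smoothed, nw: int = 15, floor: float = 1e-12) -> list[FrameFeatures]:
    """Non-overlapping log-energy frames of length ``nw``.

    Frames end at samples nw, 2nw, ...; a trailing partial frame is
    discarded.  Frame energy is the mean squared amplitude, floored at
    ``floor`` before the log; the derivative feature of the first frame is 0
    by convention.
    """
    x = np.asarray(smoothed, dtype=float)
    if x.size < 2 * nw:
        raise ValidationError(f"need at least {2 * nw} samples for 2 frames")
    n_frames = x.size // nw
    mat = x[: n_frames * nw].reshape(n_frames, nw)
    energy = np.maximum(np.mean(mat * mat, axis=1), floor)
    e = np.log(energy)
    de = np.empty_like(e)
    de[0] = 0.0
    de[1:] = np.diff(e)
    return [
        FrameFeatures(i, (i + 1) * nw, float(e[i]), float(de[i]))
        for i in range(n_frames)
    ]


def classify_frames(
    features: list[FrameFeatures], cfg: AlgorithmConfig | None = None
) -> tuple[np.ndarray, GmmModel]:
    """Label each frame inspiration/expiration with a 3-component mixture.

    Expiration is the single component with the lowest mean energy; the
    remaining two components (rising slopes: maximal mean energy
    derivative; falling slopes: minimal) form the inspiration class.  Frames
    are assigned by comparing the expiration component density against the
    sum of the two inspiration component densities, each weighted by its
    fitted mixing proportion.
    """
    cfg = cfg or AlgorithmConfig()
    if len(features) < 9:
        raise ValidationError("need at least 9 frames for a 3-component mixture")
    X = np.array([[f.e, f.de] for f in features])
    if np.ptp(X[:, 0]) < 1e-9:
        raise DegenerateSignal("frame energies are constant: nothing to classify")
    gmm = fit_gmm(X, 3, cfg)
    exp_comp = int(np.argmin(gmm.means[:, 0]))
    insp_comps = [j for j in range(3) if j != exp_comp]
    dens = np.column_stack(
        [gmm.weights[j] * gmm.component_pdf(X, j) for j in range(3)]
    )
    p_exp = dens[:, exp_comp]
    p_insp = dens[:, insp_comps].sum(axis=1)
    labels = np.where(p_insp > p_exp, LABEL_INSPIRATION, LABEL_EXPIRATION)
    if labels.min() == labels.max():
        raise DegenerateSignal("all frames fell into a single class")
    return labels, gmm


def extract_inspirations(labels, nw: int = 15) -> list[BreathInterval]:
    """Turn maximal runs of inspiration frames into neural breath intervals."""
    lab = np.asarray(labels)
    if lab.size == 0:
        raise ValidationError("empty label sequence")
    insp = lab == LABEL_INSPIRATION
    padded = np.concatenate(([False], insp, [False]))
    d = np.diff(padded.astype(int))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return [
        BreathInterval("neural", b, int(s * nw), int(e * nw))
        for b, (s, e) in enumerate(zip(starts, ends))
    ]


def paw_peaks(
    rec: TitrationRecording, inspirations: list[BreathInterval]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-breath airway-pressure peaks over the neural inspirations.

    Paw is reconstructed as NAVA_level * EAdi.  Returns (peak sample
    indices, peak Paw values), ordered by breath; ties within a breath break
    to the earliest sample.
    """
    paw = rec.paw()
    idx = np.empty(len(inspirations), dtype=int)
    val = np.empty(len(inspirations), dtype=float)
    for k, iv in enumerate(inspirations):
        seg = paw[iv.s: iv.e]
        p = int(np.argmax(seg))  # argmax returns the first maximum
        idx[k] = iv.s + p
        val[k] = seg[p]
    return idx, val
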