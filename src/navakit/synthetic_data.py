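"""Seeded simulator of NAVA titration sessions with known ground truth.

The generator emulates the clinical titration protocol: assist is first
reduced from a prior working level to zero, then stepped up by 0.1 cmH2O/µV
every 20 s to a maximum, after which the clinician sets the level back down.
Breathing is quasi-periodic (cycles of 2–4 s), each breath an EAdi half-sine
burst riding on a small tonic baseline.  While the assist is below a planted
adequate level the burst amplitude is constant, so peak airway pressure
(level x EAdi) rises linearly with the staircase (1st response); once the
assist crosses the planted level the respiratory drive is down-regulated so
that peak pressure — and with it tidal volume — plateaus (2nd response).
Inspiratory flow is a half-sine lobe integrating to the breath's tidal
volume; expiration is a volume-conserving decaying negative lobe.  White
measurement noise and occasional sub-100-ms false-trigger blips complete
the picture.  Everything is reproducible from the seed.

What this simulator does NOT model: cardiac contamination of EAdi, dynamic
(non-instantaneous) down-regulation, resistance/elastance lung mechanics,
or leaks.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io_signals import TitrationRecording, write_recording


@dataclass(frozen=True)
class SimulationParams:
    """Conditions of one simulated titration session.

    The protocol constants (sampling rate, step size and duration, breath
    period range) follow the clinical procedure the identification method
    targets; amplitudes and mechanics are chosen to resemble a critically
    ill adult on partial support (tidal volumes of a few hundred mL, peak
    pressures of tens of cmH2O).
    """

    fs: float = 62.5                    # Hz
    lead_in_s: float = 20.0             # prior assist before reduction to zero
    lead_in_level: float = 1.5          # cmH2O/µV during the lead-in
    rest_s: float = 40.0                # unassisted interval before the staircase
    post_s: float = 120.0               # after the staircase
    post_level: float | None = None     # level set after titration (default: truth)
    step_size: float = 0.1              # cmH2O/µV per titration step
    step_duration: float = 20.0         # s per step
    max_level: float = 5.0              # cmH2O/µV, top of the staircase
    true_nava_al: float = 2.5           # planted transition level, cmH2O/µV
    eadi_baseline: float = 0.5          # tonic EAdi, µV
    eadi_amp_phase1: float = 10.0       # peak EAdi while under-assisted, µV
    paw_target: float | None = None     # phase-2 peak Paw plateau, cmH2O
    phase2_creep: float = 0.0           # fractional Paw rise per cmH2O/µV above
                                        # the transition; 0 = hard plateau,
                                        # >0 emulates partial down-regulation
                                        # (a residual "less steep increase")
    compliance: float = 0.02            # L per cmH2O: maps peak Paw to extra Vt
    vt_base: float = 0.25               # L, unassisted spontaneous tidal volume
    breath_period_range: tuple[float, float] = (2.0, 4.0)  # s
    insp_frac: float = 0.4              # inspiratory fraction of the cycle
    amp_jitter: float = 0.05            # relative SD of breath-to-breath amplitude
    eadi_noise_sd: float = 0.1          # µV
    flow_noise_sd: float = 0.01         # L/s
    artifact_rate_per_min: float = 2.0  # false-trigger blips per minute
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.true_nava_al < self.max_level:
            raise ValidationError("true_nava_al must lie inside (0, max_level)")
        if self.step_size <= 0 or self.step_duration <= 0:
            raise ValidationError("step_size and step_duration must be > 0")
        lo, hi = self.breath_period_range
        if not (1.0 <= lo < hi <= 4.0):
            raise ValidationError("breath period range must lie within [1, 4] s")
        if self.insp_frac <= 0 or self.insp_frac >= 1:
            raise ValidationError("insp_frac must lie in (0, 1)")

    @property
    def n_steps(self) -> int:
        return int(round(self.max_level / self.step_size))

    def resolved_paw_target(self) -> float:
        # Continuity at the transition: phase-1 peak Paw at the planted level.
        if self.paw_target is not None:
            return self.paw_target
        return self.true_nava_al * self.eadi_amp_phase1

    def resolved_post_level(self) -> float:
        return self.true_nava_al if self.post_level is None else self.post_level

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["breath_period_range"] = list(self.breath_period_range)
        return d


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth of one simulated session (0-based, half-open intervals)."""

    window_start: int
    window_end: int
    transition_sample: int
    transition_level: float
    true_nava_al: float
    neural_intervals: list[tuple[int, int]] = field(default_factory=list)
    flow_intervals: list[tuple[int, int]] = field(default_factory=list)
    vt: list[float] = field(default_factory=list)
    paw_peak: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "window_start": self.window_start,
            "window_end": self.window_end,
            "transition_sample": self.transition_sample,
            "transition_level": self.transition_level,
            "true_nava_al": self.true_nava_al,
            "neural_intervals": [list(iv) for iv in self.neural_intervals],
            "flow_intervals": [list(iv) for iv in self.flow_intervals],
            "vt": self.vt,
            "paw_peak": self.paw_peak,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            window_start=d["window_start"],
            window_end=d["window_end"],
            transition_sample=d["transition_sample"],
            transition_level=d["transition_level"],
            true_nava_al=d["true_nava_al"],
            neural_intervals=[tuple(iv) for iv in d["neural_intervals"]],
            flow_intervals=[tuple(iv) for iv in d["flow_intervals"]],
            vt=list(d["vt"]),
            paw_peak=list(d["paw_peak"]),
        )


def _half_sine(n: int) -> np.ndarray:
    # midpoint-sampled so both edge samples are strictly positive
    return np.sin(np.pi * (np.arange(n) + 0.5) / n)


def _level_profile(p: SimulationParams) -> tuple[np.ndarray, int, int]:
    """Per-sample assist level; returns (level, titration start, titration end)."""
    n_lead = int(round(p.lead_in_s * p.fs))
    n_rest = int(round(p.rest_s * p.fs))
    n_step = int(round(p.step_duration * p.fs))
    n_post = int(round(p.post_s * p.fs))
    steps = (np.arange(p.n_steps) + 1) * p.step_size
    level = np.concatenate([
        np.full(n_lead, p.lead_in_level),
        np.zeros(n_rest),
        np.repeat(steps, n_step),
        np.full(n_post, p.resolved_post_level()),
    ])
    n_ts = n_lead + n_rest
    n_te = n_ts + p.n_steps * n_step
    return level, n_ts, n_te


def generate_session(p: SimulationParams) -> tuple[TitrationRecording, GroundTruth]:
    """Simulate one titration session and its planted ground truth."""
    rng = np.random.default_rng(p.seed)
    level, n_ts, n_te = _level_profile(p)
    n = level.size
    eadi = np.full(n, p.eadi_baseline)
    flow = np.zeros(n)
    paw_target = p.resolved_paw_target()

    # planted transition: first staircase sample at or above the true level
    grid_level = math.ceil(p.true_nava_al / p.step_size - 1e-9) * p.step_size
    trans_idx = n_ts + int(np.argmax(level[n_ts:n_te] >= grid_level - 1e-12))

    neural, flows, vts, peaks = [], [], [], []
    t = 0.0
    lo, hi = p.breath_period_range
    while True:
        period = rng.uniform(lo, hi)
        s0 = int(round(t * p.fs))
        ni = int(round(p.insp_frac * period * p.fs))
        ne = int(round(period * p.fs)) - ni
        if s0 + ni + ne >= n:
            break
        level_b = level[s0]
        if level_b < grid_level:
            peak_eadi = p.eadi_amp_phase1          # 1st response: fixed drive
        else:
            # 2nd response: drive down-regulated so peak Paw plateaus, with a
            # residual shallow rise (partial down-regulation)
            target = paw_target * (1.0 + p.phase2_creep * (level_b - grid_level))
            peak_eadi = target / level_b
        peak_eadi *= max(1.0 + rng.normal(0.0, p.amp_jitter), 0.1)
        peak_eadi = max(peak_eadi, p.eadi_baseline + 0.5)
        eadi[s0: s0 + ni] += (peak_eadi - p.eadi_baseline) * _half_sine(ni)
        # exact noiseless Paw peak of this breath (a burst may straddle a
        # staircase step, so the product is evaluated on the waveforms)
        paw_peak = float(np.max(level[s0: s0 + ni] * eadi[s0: s0 + ni]))
        vt = p.vt_base + p.compliance * level_b * peak_eadi
        ti = ni / p.fs
        flow[s0: s0 + ni] += (np.pi * vt / (2.0 * ti)) * _half_sine(ni)
        tau = (ne / p.fs) / 3.0
        b_amp = vt / (tau * (1.0 - math.exp(-ne / (p.fs * tau))))
        flow[s0 + ni: s0 + ni + ne] -= b_amp * np.exp(
            -np.arange(ne) / (p.fs * tau)
        )
        neural.append((s0, s0 + ni))
        flows.append((s0, s0 + ni))
        vts.append(vt)
        peaks.append(paw_peak)
        t += period

    # false-trigger artifacts: sub-100-ms blips outside inspirations
    n_art = rng.poisson(p.artifact_rate_per_min * n / p.fs / 60.0)
    blip = _half_sine(4)  # 64 ms at 62.5 Hz
    insp_mask = np.zeros(n, dtype=bool)
    for s, e in neural:
        insp_mask[s:e] = True
    for _ in range(n_art):
        pos = int(rng.integers(0, n - 4))
        if insp_mask[pos: pos + 4].any():
            continue
        flow[pos: pos + 4] += 0.08 * blip
        eadi[pos: pos + 4] += 1.0 * blip

    if p.eadi_noise_sd > 0:
        eadi = eadi + rng.normal(0.0, p.eadi_noise_sd, n)
    np.maximum(eadi, 0.0, out=eadi)
    if p.flow_noise_sd > 0:
        flow = flow + rng.normal(0.0, p.flow_noise_sd, n)

    rec = TitrationRecording(fs=p.fs, nava_level=level, eadi=eadi, flow=flow)
    truth = GroundTruth(
        window_start=n_ts,
        window_end=n_te,
        transition_sample=trans_idx,
        transition_level=float(grid_level),
        true_nava_al=p.true_nava_al,
        neural_intervals=neural,
        flow_intervals=flows,
        vt=vts,
        paw_peak=peaks,
    )
    return rec, truth


#: Planted transition levels cycled through by make_fixture_suite (cmH2O/µV).
FIXTURE_TRANSITION_GRID = (1.5, 2.0, 2.5, 3.0, 3.5)


def session_params_for(seed: int, index: int) -> SimulationParams:
    """Deterministic per-session parameters for a fixture suite."""
    child = (seed * 10007 + index * 97 + 1) % (2**31 - 1)
    truth = FIXTURE_TRANSITION_GRID[index % len(FIXTURE_TRANSITION_GRID)]
    return SimulationParams(true_nava_al=truth, seed=child)


def make_fixture_suite(out_dir, n_sessions: int, seed: int) -> dict:
    """Write a suite of simulated sessions + truths + manifest to a directory.

    Emits ``session_###.csv`` (recording), ``session_###.truth.json`` and a
    ``manifest.json`` listing the parameters of every session.  Re-running
    with the same arguments reproduces every file byte for byte.
    """
    os.makedirs(out_dir, exist_ok=True)
    entries = []
    for i in range(n_sessions):
        params = session_params_for(seed, i)
        rec, truth = generate_session(params)
        csv_path = os.path.join(out_dir, f"session_{i:03d}.csv")
        truth_path = os.path.join(out_dir, f"session_{i:03d}.truth.json")
        write_recording(rec, csv_path)
        with open(truth_path, "w") as fh:
            json.dump(truth.to_dict(), fh, sort_keys=True, indent=1)
        with open(csv_path, "rb") as fh:
            digest = hashlib.sha256(fh.read()).hexdigest()
        entries.append({
            "csv": os.path.basename(csv_path),
            "truth": os.path.basename(truth_path),
            "sha256": digest,
            "params": params.to_dict(),
        })
    manifest = {"seed": seed, "n_sessions": n_sessions, "sessions": entries}
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
    return manifest
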