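import numpy as np
import pytest

from navakit import AlgorithmConfig, SimulationParams, generate_session


@pytest.fixture(scope="session")
def cfg():
    return AlgorithmConfig()


@pytest.fixture(scope="session")
def default_session():
    """One default simulated titration session (planted truth 2.5)."""
    return generate_session(SimulationParams(seed=7))


@pytest.fixture(scope="session")
def quiet_session():
    """A noiseless, artifact-free session for exact structural checks."""
    params = SimulationParams(
        seed=11, eadi_noise_sd=0.0, flow_noise_sd=0.0,
        artifact_rate_per_min=0.0, amp_jitter=0.0,
    )
    return generate_session(params)


def brute_force_line_segments(signal, tol):
    """Independent maximal-collinear-run finder (quadratic re-verification).

    From each start, anchor a line on the first two samples and find the
    largest end such that every sample of the run lies on the line within
    tol, re-checking the whole run for each candidate end.
    """
    x = np.asarray(signal, dtype=float)
    n = x.size
    bounds = []
    s = 0
    while s < n:
        if s == n - 1:
            bounds.append((s, n))
            break
        a = x[s + 1] - x[s]
        b = x[s] - a * s
        e = s + 2
        while e < n:
            run = np.arange(s, e + 1)
            if np.all(np.abs(x[s: e + 1] - (a * run + b)) <= tol):
                e += 1
            else:
                break
        bounds.append((s, e))
        s = e
    return bounds


def random_piecewise_linear(rng, max_len=10_000):
    """A random exactly-piecewise-linear signal with jumps between pieces."""
    n = int(rng.integers(10, max_len))
    k = int(rng.integers(1, 8))
    cuts = np.sort(rng.choice(np.arange(2, max(n - 2, 3)), size=min(k, n // 3),
                              replace=False))
    pieces = np.split(np.arange(n), cuts)
    sig = np.empty(n)
    for piece in pieces:
        a = rng.choice([0.0, rng.normal()])
        b = rng.normal() * 5
        sig[piece] = a * (piece - piece[0]) + b
    return sig
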