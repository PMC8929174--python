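import numpy as np
import pytest

from kurafit import (
    AnalyticPhaseSet,
    MeasureStack,
    TimeCourseSet,
    euler_forward_phases,
)

DT = 2.0
BAND = (0.05, 0.075)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_tone_tc(freq_hz, T=300, dt=DT, amplitudes=None, n_regions=2):
    """Pure sinusoid time-course set (identical or per-region frequencies)."""
    t = np.arange(T) * dt
    freqs = np.broadcast_to(np.atleast_1d(freq_hz), (n_regions,))
    amps = np.ones(n_regions) if amplitudes is None else np.asarray(amplitudes)
    data = amps[:, None] * np.cos(2 * np.pi * freqs[:, None] * t)
    return TimeCourseSet(data=data, dt=dt)


def make_phase_set(phases, dt=DT, band=BAND):
    return AnalyticPhaseSet(
        phases=np.asarray(phases, dtype=float),
        amplitudes=np.ones_like(np.asarray(phases, dtype=float)),
        band=band,
        dt=dt,
    )


def make_euler_phase_set(rng, r=6, T=80, k_sd=0.4):
    """Phases generated by the estimator's own forward recursion (exact oracle)."""
    K = rng.normal(0.0, k_sd, size=(r, r))
    np.fill_diagonal(K, 1.0)
    omega = rng.uniform(0.7, 0.86, size=r)
    phi0 = rng.uniform(0.0, 2 * np.pi, size=r)
    phases = euler_forward_phases(K, omega, phi0, T)
    return make_phase_set(phases), K, omega


def make_noise_stack(rng, s=24, r=20, symmetric=False, measure="K"):
    tensor = rng.normal(size=(s, r, r))
    if symmetric:
        tensor = 0.5 * (tensor + tensor.transpose(0, 2, 1))
    return MeasureStack(
        tensor=tensor,
        measure=measure,
        subject_ids=[f"s{i:02d}" for i in range(s)],
        symmetric=symmetric,
    )


@pytest.fixture
def euler_phase_set(rng):
    return make_euler_phase_set(rng)
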