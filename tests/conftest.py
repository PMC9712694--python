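"""Shared fixtures: small synthetic recordings built once per session."""

import numpy as np
import pytest

from interopipe.simulate import (
    ProtocolEvent,
    ProtocolSchedule,
    SimConfig,
    generate_protocol,
    simulate_breathing,
    simulate_heartbeats,
)


@pytest.fixture(scope="session")
def protocol():
    return generate_protocol(seed=1)


def free_breathing_config(seed=0, duration_s=300.0, rate=0.25, **kw):
    """Free-breathing config used by coupling and detection tests."""
    defaults = dict(
        duration_s=duration_s,
        breathing_mode="free",
        free_breathing_rate=rate,
        breathing_jitter=0.1,
        rsa_gain=0.15,
        rsa_lag_s=10.0,
        lf_gain=0.02,
        seed=seed,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


def rest_only_schedule(duration_s: float) -> ProtocolSchedule:
    return ProtocolSchedule((ProtocolEvent("rest", 0.0, duration_s),))


@pytest.fixture(scope="session")
def coupled_record(protocol):
    """300 s free-breathing record with RSA at a 10 s breathing-to-heart lag."""
    cfg = free_breathing_config(seed=5)
    breathing = simulate_breathing(protocol, cfg)
    beat_times = simulate_heartbeats(breathing, cfg)
    return cfg, breathing, beat_times


def match_fraction(detected: np.ndarray, reference: np.ndarray, tol_s: float) -> float:
    """Fraction of reference events with a detection within tol_s."""
    if reference.size == 0:
        return np.nan
    idx = np.searchsorted(detected, reference)
    idx = np.clip(idx, 1, detected.size - 1)
    nearest = np.minimum(
        np.abs(reference - detected[idx - 1]), np.abs(reference - detected[idx])
    )
    return float(np.mean(nearest <= tol_s))
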