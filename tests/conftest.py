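import numpy as np
import pytest

from hrvseizure import RRGenConfig, RRSeries, gen_rr_series


def constant_rr(n: int = 120, rr_ms: float = 800.0, t0: float = 0.0) -> RRSeries:
    """n identical intervals starting at t0."""
    rr = np.full(n, rr_ms)
    beat_times = t0 + np.concatenate([[0.0], np.cumsum(rr) / 1000.0])
    return RRSeries(beat_times, rr)


@pytest.fixture(scope="session")
def interictal_rr() -> RRSeries:
    """10 min of stationary synthetic RR data (default resting physiology)."""
    rr, _ = gen_rr_series(RRGenConfig(duration=600.0, seed=42))
    return rr


@pytest.fixture(scope="session")
def preictal_rr() -> RRSeries:
    """17 min record with a sympathetic-activation ramp in the final 4 min."""
    rr, _ = gen_rr_series(
        RRGenConfig(
            duration=1020.0, preictal_onset=780.0, preictal_ramp=180.0, seed=42
        )
    )
    return rr
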