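import numpy as np
import pytest

from pairflight import kinematics


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def smooth_raw_trajectory(pair_id: str, agent: int, t0: float, t1: float,
                          seed: int, rate: float = 60.0) -> kinematics.RawTrajectory:
    """A smooth random flight-like trajectory sampled at ``rate`` over [t0, t1]."""
    rng = np.random.default_rng(seed)
    n = int(round((t1 - t0) * rate)) + 1
    t = t0 + np.arange(n) / rate
    # superposition of a drift and a few low-frequency sinusoids per axis
    pos = np.zeros((n, 3))
    pos[:, 0] = 4.0 * (t - t0)
    for ax in range(3):
        amps = rng.uniform(0.05, 0.3, size=3)
        freqs = rng.uniform(0.5, 2.0, size=3)
        phases = rng.uniform(0, 2 * np.pi, size=3)
        pos[:, ax] += sum(a * np.sin(2 * np.pi * f * t + p)
                          for a, f, p in zip(amps, freqs, phases))
    return kinematics.RawTrajectory(pair_id, agent, t, pos, rate)


def pair_record_with_overlap_length(pair_id: str, n: int, seed: int,
                                    rate: float = 180.0) -> kinematics.PairRecord:
    """A pair whose co-presence window has exactly n samples at ``rate``."""
    t1 = (n - 1) / rate
    raw1 = smooth_raw_trajectory(pair_id, 1, 0.0, t1, seed, rate=rate)
    raw2 = smooth_raw_trajectory(pair_id, 2, 0.0, t1, seed + 1, rate=rate)
    rec = kinematics.make_pair_record(raw1, raw2, rate)
    assert len(rec.series_1) == n
    return rec
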