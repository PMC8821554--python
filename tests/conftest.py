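import numpy as np
import pytest

from msna_cortex.synthetic import (CardiacSeries, CohortSpec, StimulusProtocol,
                                   gen_cardiac, gen_protocol,
                                   protocol_duration)


def make_protocol(pulse_intervals, r_times=None, variant="meg"):
    """Protocol stub from explicit cardiac-interval indices."""
    pi = np.atleast_2d(np.asarray(pulse_intervals, dtype=int))
    if r_times is None:
        r_times = np.arange(pi.max() + 10, dtype=float)
    times = np.asarray(r_times)[pi] + 0.2
    return StimulusProtocol(variant=variant, pulse_intervals=pi,
                            pulse_times=times,
                            iti_seq=np.full(pi.shape[0], 30.0))


@pytest.fixture
def small_spec():
    return CohortSpec(n_subjects=6, seed=7, n_trials=8, iti_menu=(14.0,))


@pytest.fixture
def cardiac_60s():
    """Regular 1 s RR over 60 s (51 R-waves)."""
    r = 1.0 + np.arange(55, dtype=float)
    return CardiacSeries(r_times=r[r < 58.0], duration=60.0)


@pytest.fixture
def study_protocol_pair():
    """One subject's cardiac series plus both protocol variants at study
    scale (72 trials, ITI 30/45/60 s)."""
    rng = np.random.default_rng(42)
    card = gen_cardiac(56.0, protocol_duration(72, (30, 45, 60), 56.0), rng)
    meg = gen_protocol(card, "meg", 72, (30, 45, 60), seed=9)
    micro = gen_protocol(card, "microneurography", 72, (30, 45, 60), seed=9)
    return card, meg, micro
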