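import warnings

import numpy as np
import pytest

import orthohrv as oh


def make_segment(rr_ms, phase_name="test", beat_times=None, min_beats=3,
                 subject_id="S1"):
    """Build a PhaseSegment directly from an interval list (ms)."""
    rr = np.asarray(rr_ms, dtype=float)
    if beat_times is None:
        beat_times = np.cumsum(rr) / 1000.0
    return oh.PhaseSegment(phase_name=phase_name, rr_ms=rr,
                           beat_times=np.asarray(beat_times, float),
                           duration_s=float(beat_times[-1]),
                           subject_id=subject_id, min_beats=min_beats)


def tone_segment(freq_hz, amp_ms=50.0, base_ms=1000.0, duration_s=300.0,
                 extra=None):
    """Segment whose tachogram is a pure tone: rr(t) = base + amp·sin(2πft)
    (plus optional extra tones), beats emitted sequentially."""
    t, beats = 0.0, []
    while t < duration_s:
        rr = base_ms + amp_ms * np.sin(2 * np.pi * freq_hz * t)
        if extra:
            for f2, a2 in extra:
                rr += a2 * np.sin(2 * np.pi * f2 * t)
        t += rr / 1000.0
        beats.append(t)
    beats = np.asarray(beats)
    rr = np.diff(np.concatenate([[0.0], beats])) * 1000.0
    return make_segment(rr, beat_times=beats)


@pytest.fixture(scope="session")
def small_cohort():
    """Shared default-scenario cohort, 12 subjects per group."""
    cfg = oh.GeneratorConfig(groups=oh.default_groups(12), seed=123)
    return oh.gen_cohort(cfg)


@pytest.fixture(scope="session")
def small_bundle(small_cohort):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return oh.analyze_cohort(small_cohort.series, small_cohort.metadata)
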