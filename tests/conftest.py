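import numpy as np
import pytest

import porecount as pc


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def three_class_features():
    """Paper-calibrated feature draws for all three classes, 800 each."""
    frames = [
        pc.sample_event_features(pc.DEFAULT_CLASSES[label], 800, seed)
        for seed, label in enumerate(("fragment", "mtDNA", "linear_dsDNA"))
    ]
    return pc.build_features(frames)


@pytest.fixture(scope="session")
def mtdna_trace_run():
    """One simulated mtDNA-only recording with baseline, bounds and events."""
    spec = pc.TraceSpec(duration_s=4.0, event_rate_hz=80.0,
                        class_mixture={"mtDNA": 1.0}, seed=7)
    trace, truth = pc.synth_trace(spec)
    baseline = pc.estimate_baseline(trace)
    bounds = pc.detect_events(trace, baseline)
    events = pc.extract_features(trace, bounds, baseline)
    return trace, truth, baseline, bounds, events
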