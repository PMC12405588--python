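import numpy as np
import pytest

from larvaction import kinematics as kin
from larvaction.synth import GenerationConfig, gen_track


@pytest.fixture(scope="session")
def straight_track():
    """Straight larva translating at 1 mm/s along +x, body length 4 mm."""
    n = 301
    t = np.arange(n) * kin.DT
    spine = np.zeros((n, 11, 2))
    for i in range(11):
        spine[:, i, 0] = -0.4 * i
    spine[:, :, 0] += (1.0 * t)[:, None]
    return kin.SpineTrack("straight", t, spine, regular=True)


@pytest.fixture(scope="session")
def static_track():
    """Motionless straight larva on the regular grid."""
    n = 120
    t = np.arange(n) * kin.DT
    spine = np.zeros((n, 11, 2))
    for i in range(11):
        spine[:, i, 0] = -0.4 * i
    return kin.SpineTrack("static", t, spine, regular=True)


@pytest.fixture(scope="session")
def crawl_track():
    """10 s of clean 1.4 Hz peristaltic crawling from the generator."""
    cfg = GenerationConfig(seed=4, duration=10.0, coord_noise_sd=0.0,
                           heading_drift_sd=0.0)
    track, truth = gen_track(cfg, [("crawl", 0.0, 10.0)])
    return kin.preprocess(track), truth


@pytest.fixture(scope="session")
def small_cohort():
    """A small labeled cohort shared by the annotation tests."""
    from larvaction.synth import gen_cohort

    cfg = GenerationConfig(seed=11, n_larvae=10, duration=80.0)
    tracks, truths = gen_cohort(cfg)
    return [kin.preprocess(t) for t in tracks], truths
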