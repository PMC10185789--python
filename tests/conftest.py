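import numpy as np
import pytest

from nwreflex import aggregate, detect, preprocess, synth
from nwreflex.signal_io import DetectionConfig


@pytest.fixture(scope="session")
def pre_cfg():
    return preprocess.PreprocessConfig()


@pytest.fixture(scope="session")
def det_cfg():
    return DetectionConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """Rendered mixed cohort: 3 SCI + 3 NDC, 3 sites, 15 trials each."""
    cfg = synth.CohortConfig(seed=1, n_sci=3, n_ndc=3, trials_per_site=15)
    return synth.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_detections(small_cohort, pre_cfg, det_cfg):
    dets = []
    for eps in small_cohort.epochs.values():
        for ep in eps:
            dets.append(detect.detect_trial(
                preprocess.preprocess_epoch(ep, pre_cfg), det_cfg))
    return dets


def noise_epoch(seed: int, noise_sd: float = 5.0):
    """A canonical noise-only epoch (no planted bursts)."""
    rng = np.random.default_rng(seed)
    gp = synth.sci_default_params()
    n = 3501
    from nwreflex.synth import _bandlimited_noise
    from nwreflex.signal_io import EMGEpoch
    return EMGEpoch(
        participant_id="X01", trial_index=0, site="FS", energy_mJ=600.0,
        sampling_rate_Hz=1000.0, t0_offset_ms=-500.0,
        samples_TA=_bandlimited_noise(n, 1000.0, noise_sd,
                                      gp.noise_band_Hz, rng),
        samples_SO=_bandlimited_noise(n, 1000.0, noise_sd,
                                      gp.noise_band_Hz, rng))
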