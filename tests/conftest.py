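import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cascade_series():
    """Deterministic binomial multiplicative cascade, 2**12 points, p = 0.3."""
    from blinkrv import binomial_cascade

    return binomial_cascade(12, 0.3)


def make_blink_eeg(seed, duration=300.0, mean_rate=18.0, alpha_target=0.8,
                   noise_sd=15.0, amplitude=100.0):
    """Synthetic two-channel EEG with known blink times (shared test harness)."""
    import blinkrv as b

    train = b.BlinkTrainSpec(
        duration=duration, mean_rate=mean_rate, alpha_target=alpha_target, seed=seed
    )
    brv = b.generate_blink_intervals(train)
    times = np.concatenate([[1.0], 1.0 + np.cumsum(brv.intervals)])
    times = tuple(t for t in times if t < duration - 0.5)
    spec = b.EEGSynthSpec(
        duration=duration, blink_times=times, seed=seed,
        template_amplitude=amplitude, noise_sd=noise_sd,
    )
    return b.synthesize_eeg(spec), times
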