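import numpy as np
import pytest

import volatilofp as v


@pytest.fixture(scope="session")
def small_study():
    """Rendered drifted study: 2 arms × 3 samples, 30 compounds."""
    cfg = v.SyntheticStudyConfig(
        n_samples_per_group=3,
        groups=(("VP0", "T1"), ("VP1", "T1")),
        n_compounds=30,
        n_discriminant=4,
        snr_range=(200.0, 500.0),
        seed=11,
    )
    return v.generate_study(cfg)


@pytest.fixture(scope="session")
def clean_study():
    """No-drift, (numerically) noise-free twin of the small study."""
    cfg = v.SyntheticStudyConfig(
        n_samples_per_group=3,
        groups=(("VP0", "T1"), ("VP1", "T1")),
        n_compounds=30,
        n_discriminant=4,
        drift_1d_max=0.0,
        drift_2d_max=0.0,
        noise_sd=1e-6,
        snr_range=(200.0, 500.0),
        seed=11,
    )
    return v.generate_study(cfg)


@pytest.fixture(scope="session")
def small_tables(small_study):
    return [v.detect_peaks(g) for g in small_study.grids]


def random_spectrum(rng, n_min=3, n_max=20):
    n = int(rng.integers(n_min, n_max + 1))
    mz = np.sort(rng.choice(np.arange(40, 351), size=n, replace=False))
    return v.MassSpectrum(mz, rng.exponential(1.0, n) + 0.01)
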