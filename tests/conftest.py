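import numpy as np
import pytest

from sersdx import CohortConfig, PeakSpec, generate_cohort, preprocess_dataset


@pytest.fixture(scope="session")
def small_cfg() -> CohortConfig:
    """A reduced cohort (fast) that keeps the full statistical structure."""
    return CohortConfig(
        n_target=14,
        n_control=10,
        replicates_per_subject=2,
        axis_start=400.0,
        axis_stop=1800.0,
        axis_step=4.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_strong_pp(small_cfg):
    """Preprocessed strong-effect (ratio 2) small cohort."""
    return preprocess_dataset(generate_cohort(small_cfg))


@pytest.fixture(scope="session")
def small_null_pp(small_cfg):
    """Preprocessed no-effect (ratio 1) small cohort."""
    return preprocess_dataset(generate_cohort(small_cfg.with_(effect_ratio=1.0, seed=12)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def separable_xy():
    """A tiny linearly separable two-class problem: one informative channel."""
    rng = np.random.default_rng(7)
    n = 24
    y = np.repeat([1.0, 0.0], n // 2)
    X = rng.normal(0, 0.05, (n, 4))
    X[:, 2] += y * 2.0  # channel 2 fully separates the classes
    return X, y


def single_peak_cfg(shape: str = "lorentzian", **kw) -> CohortConfig:
    """One isolated peak on a flat, noise-free background."""
    defaults = dict(
        n_target=1,
        n_control=1,
        replicates_per_subject=1,
        shared_peaks=(PeakSpec(1000.0, 20.0, 1.0, shape),),
        effect_bands=((1000.0, 20.0),),
        noise_sd=0.0,
        subject_sd=0.0,
        peak_jitter_sd=0.0,
        baseline_scale=0.0,
    )
    defaults.update(kw)
    return CohortConfig(**defaults)
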