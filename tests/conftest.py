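import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mirfluid as mf

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def panel():
    return mf.MarkerPanel()


@pytest.fixture
def small_panel():
    """A 3-target, 2-fluid panel for cheap exact-arithmetic tests."""
    return mf.MarkerPanel(
        target_markers=("mA", "mB", "mC"),
        reference_markers=("ref1", "ref2"),
        fluid_classes=("fluidX", "fluidY"),
    )


@pytest.fixture
def study_config():
    return mf.default_config(seed=7)


@pytest.fixture
def study_profiles(study_config):
    return mf.simulate_profiles(study_config)


def make_separated_profiles(
    panel, n_per_class=50, separation=6.0, seed=0, missing_rate=0.0
):
    """Well-separated Gaussian classes: class c has mean separation*e_c-ish."""
    rng = np.random.default_rng(seed)
    d = panel.n_targets
    profiles = []
    for ci, fluid in enumerate(panel.fluid_classes):
        mean = np.zeros(d)
        mean[ci % d] = separation
        mean[(ci + 1) % d] = separation / 2 * (1 if ci % 2 else -1)
        X = rng.normal(size=(n_per_class, d)) + mean
        mask_draw = rng.random((n_per_class, d)) >= missing_rate
        for i in range(n_per_class):
            mask = mask_draw[i]
            if not mask.any():
                mask[0] = True
            profiles.append(
                mf.DeltaCqProfile(
                    sample_id=f"{fluid}_{i}",
                    values=np.where(mask, X[i], np.nan),
                    mask=mask,
                    fluid_label=fluid,
                )
            )
    return profiles


def make_identical_profiles(panel, n_per_class=50, seed=0):
    """All classes share one standard-normal distribution (chance level)."""
    rng = np.random.default_rng(seed)
    d = panel.n_targets
    profiles = []
    for fluid in panel.fluid_classes:
        X = rng.normal(size=(n_per_class, d))
        for i in range(n_per_class):
            profiles.append(
                mf.DeltaCqProfile(
                    sample_id=f"{fluid}_{i}",
                    values=X[i],
                    mask=np.ones(d, dtype=bool),
                    fluid_label=fluid,
                )
            )
    return profiles


def random_mvn_params(d, rng, scale=1.0):
    A = rng.normal(size=(d, d))
    cov = A @ A.T / d + np.eye(d)
    return mf.MVNParams(mean=rng.normal(size=d) * scale, covariance=cov * scale)
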