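import pytest

from layerdig import (
    BirdRecord,
    FeedComposition,
    ManureAssay,
    SimConfig,
    TrialDataset,
    simulate_trial,
)
from layerdig.synthetic import default_feed, default_line_params, default_sim_config


@pytest.fixture
def feed() -> FeedComposition:
    return default_feed()


@pytest.fixture
def small_dataset(feed) -> TrialDataset:
    """Two hand-written birds with assays; values typical of layers."""
    birds = [
        BirdRecord("h1", "A", dfc=140.0, dmw=120.0, dbw=1700.0,
                   eggs_laid=7, mean_egg_weight=60.0),
        BirdRecord("h2", "B", dfc=122.0, dmw=146.0, dbw=1680.0,
                   eggs_laid=8, mean_egg_weight=58.0),
    ]
    assays = {
        "h1": ManureAssay("h1", adm=252.0, dm_ad=1000.0, ash_ad=240.0,
                          nitrogen_ad=38.0, fat_ad=30.0, uric_acid_ad=40.0),
        "h2": ManureAssay("h2", adm=260.0, dm_ad=1000.0, ash_ad=250.0,
                          nitrogen_ad=36.0, fat_ad=28.0, uric_acid_ad=35.0),
    }
    return TrialDataset(birds=birds, assays=assays, feed=feed)


@pytest.fixture
def zero_noise_trial():
    """Default two-line study conditions with assay noise switched off."""
    cfg = default_sim_config(seed=11, assay_noise_cv=0.0)
    return simulate_trial(cfg)


@pytest.fixture
def noisy_trial():
    cfg = default_sim_config(seed=5)
    return simulate_trial(cfg)


def make_config(seed: int, n_a: int = 50, n_b: int = 50, noise_cv: float = 0.02) -> SimConfig:
    params = default_line_params(assay_noise_cv=noise_cv)
    params["A"].n_birds = n_a
    params["B"].n_birds = n_b
    return SimConfig(feed=default_feed(), lines=params, seed=seed)
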