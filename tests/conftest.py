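import numpy as np
import pandas as pd
import pytest

from matperc import (
    ObserverModel,
    StimulusDesign,
    generate_stimulus_set,
    simulate_ratings,
    simulate_triplets,
    video_metadata,
)
from matperc.observers import latent_attribute_table


@pytest.fixture(scope="session")
def small_design() -> StimulusDesign:
    """Full 18-exemplar class layout, but short/light videos for speed."""
    return StimulusDesign(
        views_per_class={c: 2 for c in ("jelly", "liquid", "smoke", "fabric", "rigid_breakable")},
        n_frames=12,
        n_points=120,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_videos(small_design):
    return generate_stimulus_set(small_design)


@pytest.fixture(scope="session")
def small_stimuli(small_videos) -> pd.DataFrame:
    return video_metadata(small_videos)


@pytest.fixture(scope="session")
def observer_model() -> ObserverModel:
    return ObserverModel()


@pytest.fixture(scope="session")
def small_ratings(small_stimuli, observer_model) -> pd.DataFrame:
    return simulate_ratings(small_stimuli, observer_model, n_observers=10, seed=21)


@pytest.fixture(scope="session")
def small_latent(small_stimuli, observer_model) -> pd.DataFrame:
    return latent_attribute_table(small_stimuli, observer_model, seed=22)


@pytest.fixture(scope="session")
def small_triplets(small_latent, observer_model) -> pd.DataFrame:
    return simulate_triplets(
        small_latent, observer_model, n_observers=10, trials_per_observer=200, seed=23
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
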