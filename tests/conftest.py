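import numpy as np
import pytest

from mi_erd import (
    BAND_ALPHA,
    SimConfig,
    bandpass_filter,
    build_feature_matrix,
    epoch_events,
    generate_recording,
)
from mi_erd.synthetic import PlantedEffect


def planted_erd_features(seed: int, erd_gap: float = 0.4, n_trials_per_class: int = 80,
                         channels: tuple[str, ...] = ("C3", "C4"),
                         noise_sigma: float = 0.5, filter_first: bool = True):
    """Full-pipeline ERD_A features with class-dependent ERD planted at
    ``channels`` (class A desynchronises by ``erd_gap``, class B does not)."""
    cfg = SimConfig(
        n_trials_per_class=n_trials_per_class,
        planted=tuple(PlantedEffect(ch, "ERD_A", -erd_gap, 0.0) for ch in channels),
        noise_sigma=noise_sigma,
        seed=seed,
    )
    rec = generate_recording(cfg)
    if filter_first:
        rec = bandpass_filter(rec)
    fm = build_feature_matrix(epoch_events(rec), BAND_ALPHA)
    return fm.values, np.asarray(fm.labels), fm


@pytest.fixture(scope="session")
def small_planted():
    """One modest planted-effect dataset shared across tests (seed fixed)."""
    X, y, fm = planted_erd_features(seed=11, erd_gap=0.5, n_trials_per_class=30)
    return X, y, fm
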