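"""Shared fixtures: small synthetic templates and cohorts, fast train configs.

Everything is generated programmatically at session scope; image sizes and
epoch counts are deliberately small so the full suite runs on one CPU.
"""

import dataclasses

import numpy as np
import pytest

from tlemri.datatypes import GMSlice, LabeledDataset, SubjectRecord
from tlemri.models import CNNSpec, TrainConfig
from tlemri.synthetic import CohortConfig, EffectConfig, generate_cohort, make_template

FAST_TRAIN = TrainConfig(learning_rate=0.05, epochs=15, validation_frequency=5, seed=0)


@pytest.fixture(scope="session")
def template64():
    return make_template(64, 64, seed=0)


def strong_cohort_config(effect: float = 0.5, noise_sd: float = 0.02, jitter: int = 1):
    """A clearly separable small-cohort configuration (both subgroups at the
    same effect so every patient carries the signal)."""
    eff = EffectConfig(medial_temporal_effect=effect, noise_sd=noise_sd, jitter_px=jitter)
    return dataclasses.replace(
        CohortConfig().scaled(n_tle=20, n_hc=30, n_lesional=10),
        lesional_effects=eff,
        nonlesional_effects=eff,
        control_effects=EffectConfig(noise_sd=noise_sd, jitter_px=jitter),
    )


@pytest.fixture(scope="session")
def strong_cohort(template64):
    return generate_cohort(template64, strong_cohort_config(), seed=1)


@pytest.fixture(scope="session")
def fast_train_cfg():
    return FAST_TRAIN


def toy_dataset(n_tle: int, n_hc: int, size: int = 8, seed: int = 0) -> LabeledDataset:
    """Tiny random-image dataset for split/metric plumbing tests."""
    rng = np.random.default_rng(seed)
    images, records = [], []
    for i in range(n_hc):
        images.append(GMSlice(pixels=rng.random((size, size))))
        records.append(SubjectRecord(subject_id=f"HC{i:03d}", group="HC"))
    for i in range(n_tle):
        images.append(GMSlice(pixels=rng.random((size, size))))
        records.append(
            SubjectRecord(
                subject_id=f"TLE{i:03d}", group="TLE", lesional=i % 2 == 0,
                seizure_free=i % 3 == 0,
            )
        )
    return LabeledDataset(images=images, records=records)
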