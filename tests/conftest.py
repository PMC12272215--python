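import numpy as np
import pytest

import eegage as E
from eegage.containers import SLEEP_STAGES, Hypnogram
from eegage.pipeline import covariances_for_recording


def rand_spd(dim: int, rng: np.random.Generator, scale: float = 1.0) -> np.ndarray:
    """A well-conditioned random SPD matrix."""
    a = rng.standard_normal((dim, dim))
    return scale * (a @ a.T + dim * 0.2 * np.eye(dim))


@pytest.fixture(scope="session")
def meditation_covsets():
    """Covariance sets (with cross-spectral) of three short meditation recordings."""
    cfg = E.GeneratorConfig(
        n_subjects=3, duration=180.0, seed=42, dropout_rate=0.001, artifact_rate=0.5
    )
    cohort = E.sample_cohort(cfg)
    covs = []
    for i, row in cohort.iterrows():
        rec = E.synthesize_recording(row, None, cfg, seed=np.random.SeedSequence([42, i]))
        cs = covariances_for_recording(rec, with_cross=True)
        assert cs is not None
        covs.append(cs)
    return covs


@pytest.fixture(scope="session")
def sleep_covsets():
    """Per-stage covariance sets of three sleep recordings covering all stages.

    The hypnogram is constructed (six epochs per stage) so every stage
    is observed with enough windows.
    """
    hyp = Hypnogram(labels=tuple(s for s in SLEEP_STAGES for _ in range(6)))
    cfg = E.GeneratorConfig(
        n_subjects=3, modality="sleep", duration=hyp.duration, seed=43,
        dropout_rate=0.001, artifact_rate=0.0,
    )
    cohort = E.sample_cohort(cfg)
    covs = []
    for i, row in cohort.iterrows():
        rec = E.synthesize_recording(row, hyp, cfg, seed=np.random.SeedSequence([43, i]))
        cs = covariances_for_recording(rec, with_cross=True)
        assert cs is not None
        covs.append(cs)
    return covs


@pytest.fixture(scope="session")
def sleep_references(sleep_covsets):
    flat = [cs for mapping in sleep_covsets for cs in mapping.values() if cs is not None]
    return (
        E.fit_tangent_reference(flat),
        E.fit_tangent_reference(flat, use_cross=True),
    )


@pytest.fixture(scope="session")
def meditation_references(meditation_covsets):
    return (
        E.fit_tangent_reference(meditation_covsets),
        E.fit_tangent_reference(meditation_covsets, use_cross=True),
    )
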