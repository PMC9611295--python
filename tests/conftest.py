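import numpy as np
import pytest

from plinet.connectivity import window_pli_matrices
from plinet.montage import default_montage
from plinet.preprocess import average_reference, decompose_bands
from plinet.synthetic import PlantedEdge, SyntheticConfig, generate_cohort

PLANTED_CHANNELS = ("F3", "P4")


@pytest.fixture(scope="session")
def montage():
    return default_montage()


def make_planted_config(seed: int, n_subjects: int = 20,
                        duration_s: float = 60.0) -> SyntheticConfig:
    """The study-analogue cohort: one beta edge coupled 0.2 (A) vs 0.8 (B)."""
    return SyntheticConfig(
        n_subjects=n_subjects,
        duration_s=duration_s,
        planted_edges=(PlantedEdge("beta", PLANTED_CHANNELS, 0.2, 0.8),),
        seed=seed,
    )


def cohort_mean_connectivity(config, bands=None):
    """Window-averaged PLI per recording; returns (conditions, matrices)."""
    conds, means = [], []
    for entry in generate_cohort(config):
        rec = average_reference(entry.recording)
        band_recs = decompose_bands(rec, bands or config.bands)
        means.append(
            {b: window_pli_matrices(r).mean(axis=0) for b, r in band_recs.items()}
        )
        conds.append(entry.condition)
    return conds, means


@pytest.fixture(scope="session")
def planted_cohort_meanconn():
    """One full four-band cohort at the planted-contrast conditions.

    Session-scoped: shared by the classification and recovery checks.
    """
    config = make_planted_config(seed=2024)
    conds, means = cohort_mean_connectivity(config)
    return config, conds, means
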