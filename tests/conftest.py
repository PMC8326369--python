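from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import ecohof as eh
from ecohof.pipeline import classifications_from_fits, fit_table
from ecohof.sequence_match import apply_hit_criteria

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_table(counts, sample_ids=None, otu_ids=None, ph=None, habitat=None) -> eh.OTUTable:
    """Small literal OTU tables for unit tests."""
    counts = np.asarray(counts)
    n_otus, n_samples = counts.shape
    sample_ids = sample_ids or [f"S{j + 1}" for j in range(n_samples)]
    otu_ids = otu_ids or [f"O{i + 1}" for i in range(n_otus)]
    ph = ph if ph is not None else np.linspace(4.0, 8.0, n_samples)
    habitat = habitat or ["grassland"] * n_samples
    meta = pd.DataFrame(
        {"pH": ph, "habitat": habitat}, index=pd.Index(sample_ids, name="sample_id")
    )
    return eh.OTUTable(pd.DataFrame(counts, index=otu_ids, columns=sample_ids), meta)


@pytest.fixture
def toy_table() -> eh.OTUTable:
    return make_table([[1, 2], [3, 4]], ph=[4.5, 7.5])


@dataclass
class EndToEnd:
    """A full synthetic reference/query study with fitted reference models."""

    pair: eh.StudyPair
    fits: dict
    classes: dict
    best_hits: dict


@pytest.fixture(scope="session")
def e2e() -> EndToEnd:
    """Reference study fitted end to end against a 300-sample query study.

    120 reference OTUs (all shared into a 150-OTU query at shared fraction
    0.8), 300 samples per study, bootstrap selection with 25 resamples.
    Session-scoped: several integration tests measure different properties of
    the same fitted system.
    """
    pair = eh.generate_study_pair(120, 150, 0.8, 300, seed=1)
    fits = fit_table(pair.reference, n_boot=25, seed=1, gradient_range=(3.63, 8.75))
    classes = classifications_from_fits(fits, 5.2, 7.0)
    best = apply_hit_criteria(pair.match_hits)
    return EndToEnd(pair=pair, fits=fits, classes=classes, best_hits=best)
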