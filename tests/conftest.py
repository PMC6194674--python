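"""Shared fixtures: small synthetic panels and fitted models.

Heavy fixtures are session-scoped so one build serves every test that
needs a trained classifier set.
"""

import numpy as np
import pytest

from fecalsource import (
    ASVTable,
    ForestParams,
    SourceProfileSpec,
    SourceTrackingModel,
    make_study_panel,
)

TINY_PARAMS = ForestParams(
    n_rank_replicates=2, n_rank_trees=150, n_train_replicates=2, n_train_trees=150
)


@pytest.fixture(scope="session")
def tiny_panel():
    """Three-source panel on a small ASV pool with freshwater background."""
    spec = SourceProfileSpec(
        sources=("Cow", "Pig", "Sewage"),
        n_asvs_total=120,
        n_signature_per_source=15,
        n_samples=8,
        depth=4_000,
        # mild intra-source dispersion: the unit fixture must be separable
        bc_targets={"Cow": 0.4, "Pig": 0.4, "Sewage": 0.3},
        seed=11,
    )
    return make_study_panel(seed=11, spec=spec, n_background_asvs=60)


@pytest.fixture(scope="session")
def tiny_training(tiny_panel):
    table, labels = tiny_panel.sample_table(seed=12)
    fecal_ids = [s for s, src in labels.items() if src != "Freshwater"]
    fecal = table.subset_samples(fecal_ids)
    return fecal, {s: labels[s] for s in fecal_ids}


@pytest.fixture(scope="session")
def tiny_fit(tiny_panel, tiny_training):
    """Fitted results on the tiny panel (small forests, fixed seed)."""
    fecal, labels = tiny_training
    model = SourceTrackingModel(fecal, labels, params=TINY_PARAMS)
    return model.fit(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
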