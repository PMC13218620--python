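"""Shared fixtures: synthetic ligand sets and a trained fusion model.

Everything is generated programmatically at session start; heavyweight
artifacts (the trained similarity model, the small evaluation report)
are session-scoped so the suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from chemfuse.activity_rules import classify_activity
from chemfuse.featurize import build_feature_matrix, build_selfies_vocab, bundle_molecule
from chemfuse.fusion_similarity import FusionConfig, FusionModel, build_pair_dataset, train_fusion
from chemfuse.synthetic import SyntheticSpec, generate_candidate_library, generate_ligand_set

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(n_ligands=300, seed=11)


@pytest.fixture(scope="session")
def small_set(small_spec):
    return generate_ligand_set(small_spec)


@pytest.fixture(scope="session")
def small_table(small_set):
    return small_set[0]


@pytest.fixture(scope="session")
def small_truth(small_set):
    return small_set[1]


@pytest.fixture(scope="session")
def small_labels(small_table):
    return [classify_activity(r.pic50) for r in small_table]


@pytest.fixture(scope="session")
def small_vocab(small_table):
    return build_selfies_vocab(small_table)


@pytest.fixture(scope="session")
def small_bundles(small_table, small_vocab):
    return [bundle_molecule(s, small_vocab) for s in small_table.smiles]


@pytest.fixture(scope="session")
def small_features(small_table):
    fm = build_feature_matrix(small_table)
    y = np.array([r.pic50 for r in small_table])
    return fm, y


@pytest.fixture(scope="session")
def trained_fusion(small_table, small_labels, small_vocab, small_bundles):
    pairs = build_pair_dataset(small_table, small_labels, max_pairs=900, seed=11)
    model = FusionModel(
        selfies_dim=len(small_vocab) + 1,
        fp_dim=1024,
        config=FusionConfig(max_epochs=10, seed=11),
        vocab=small_vocab,
    )
    train_fusion(model, pairs, small_bundles)
    return model


@pytest.fixture(scope="session")
def small_candidates(small_spec):
    return generate_candidate_library(small_spec, n_candidates=200, analog_fraction=0.25)
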